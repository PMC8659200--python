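"""Peptide physicochemical profiling: GRAVY, net charge, isoelectric point,
and the subgroup i/ii call for circular bacteriocin cores.

Circular (head-to-tail cyclized) peptides have no free termini — the
N- and C-terminal residues are joined by an amide bond — so ``cyclic``
mode drops both terminal ionizable groups from the charge model.

Subgroup i members are highly cationic (reported pI generally above 10);
subgroup ii members are near-neutral and hydrophobic. Because a cyclic
peptide with no acidic residues has *no* isoelectric point (its charge
never crosses zero), classification is driven by net charge at pH 7 and
GRAVY rather than by pI.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values. Defaults are the EMBOSS set."""

    side_chain: dict = field(
        default_factory=lambda: {
            "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5,
        }
    )
    n_terminus: float = 8.6
    c_terminus: float = 3.6

    def __post_init__(self) -> None:
        for k, v in {**self.side_chain, "Nterm": self.n_terminus, "Cterm": self.c_terminus}.items():
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa for {k} outside (0, 14): {v}")


BASIC = {"K", "R", "H"}
ACIDIC = {"D", "E", "C", "Y"}


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle hydropathy.

    X is excluded from both the sum and the length.
    """
    vals = [KYTE_DOOLITTLE[r] for r in sequence if r != "X"]
    if not vals:
        raise ValueError("GRAVY undefined: empty or all-X sequence")
    return sum(vals) / len(vals)


def net_charge(sequence: str, pH: float, mode: str = "linear",
               pka: PkaTable = PkaTable()) -> float:
    """Henderson-Hasselbalch net charge in elementary units.

    Basic groups contribute +1/(1+10^(pH-pKa)); acidic groups contribute
    -1/(1+10^(pKa-pH)). ``cyclic`` mode omits both terminal groups.
    """
    if not (0.0 < pH < 14.0):
        raise ValueError("pH must be in (0, 14)")
    if mode not in ("linear", "cyclic"):
        raise ValueError(f"unknown mode {mode!r}")
    charge = 0.0
    for res in sequence:
        pk = pka.side_chain.get(res)
        if pk is None:
            continue
        if res in BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pk))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pk - pH))
    if mode == "linear":
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
        charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    return charge


def isoelectric_point(sequence: str, mode: str = "linear",
                      pka: PkaTable = PkaTable(), tol: float = 1e-4):
    """pH where net charge is zero, by bisection on [0.001, 13.999].

    Returns None when the charge function has no zero crossing on the
    interval (e.g. a cyclic peptide with basic residues only) —
    "undefined" is a value here, not an error.
    """
    lo, hi = 0.001, 13.999
    c_lo = net_charge(sequence, lo, mode, pka)
    c_hi = net_charge(sequence, hi, mode, pka)
    if not (c_lo > 0.0 > c_hi):
        return None  # no strict sign change: charge never crosses zero
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, mode, pka)
        if c > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PhyschemProfile:
    gravy: float
    net_charge_pH7: float
    pI_linear: float | None
    pI_cyclic: float | None
    length: int
    subgroup_call: str  # 'i' | 'ii' | 'ambiguous'

    def __post_init__(self) -> None:
        if not (-4.5 <= self.gravy <= 4.5):
            raise ValueError(f"GRAVY out of Kyte-Doolittle bounds: {self.gravy}")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Charge/hydropathy cutoffs for the subgroup call (cyclic core mode)."""

    min_charge_subgroup_i: float = 2.0
    neutral_band: tuple[float, float] = (-1.0, 1.0)
    min_gravy_subgroup_ii: float = 0.0


def classify_subgroup(net_charge_ph7: float, gravy_value: float,
                      thresholds: ClassifierThresholds = ClassifierThresholds()) -> str:
    """Subgroup i (cationic) vs ii (neutral, hydrophobic) vs ambiguous."""
    if net_charge_ph7 >= thresholds.min_charge_subgroup_i:
        return "i"
    lo, hi = thresholds.neutral_band
    if lo <= net_charge_ph7 <= hi and gravy_value >= thresholds.min_gravy_subgroup_ii:
        return "ii"
    return "ambiguous"


def profile_peptide(core_sequence: str, pka: PkaTable = PkaTable(),
                    thresholds: ClassifierThresholds = ClassifierThresholds()) -> PhyschemProfile:
    """Full physicochemical profile of a (presumed cyclic) core peptide."""
    g = gravy(core_sequence)
    q7 = net_charge(core_sequence, 7.0, "cyclic", pka)
    return PhyschemProfile(
        gravy=g,
        net_charge_pH7=q7,
        pI_linear=isoelectric_point(core_sequence, "linear", pka),
        pI_cyclic=isoelectric_point(core_sequence, "cyclic", pka),
        length=len(core_sequence),
        subgroup_call=classify_subgroup(q7, g, thresholds),
    )
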
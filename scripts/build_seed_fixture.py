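"""Regenerate the bundled SYNTHETIC seed-set fixture.

The 19 characterized circular bacteriocins (and their transporter /
SpoIIM / accessory proteins) are referenced by name in the literature,
but no sequence set ships with this package's sources. The bundled
default seed set is therefore a synthetic stand-in generated here,
deterministically, with the documented family structure and
physicochemistry:

* subgroup i precursors are cationic (several K/R in the core, aromatic
  C-terminal residue), subgroup ii precursors are neutral/hydrophobic,
  end in alanine, and carry an asparaginyl (leader ends in N) cleavage
  site;
* family structure mirrors the known groupings: amylocyclicin /
  amylocyclicin CMW1 / enterocin NKR-5-3B are one family; enterocin
  AS-48 / pumilarin / BacA another; the six subgroup ii bacteriocins a
  third; circularin A and thermocin 485 are identical peptides;
  the rest are singleton-like;
* leader lengths span the documented 2-48 residue range.

Run from the repository root:  python scripts/build_seed_fixture.py
Output: src/cyclomine/data/{seeds_synthetic.faa, seed_roles_synthetic.tsv,
cleavage_sites_synthetic.tsv}
"""
from __future__ import annotations

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cyclomine.io import write_protein_fasta  # noqa: E402
from cyclomine.models import ProteinRecord  # noqa: E402
from cyclomine.simulate import mutate_to_identity  # noqa: E402

RNG = np.random.default_rng(7218)

SUBGROUP_I_CORE_POOL = "AGLIVFSTMNQ"  # aliphatic baseline + polar spacers
NEUTRAL_POOL = "AGLIVFSTMWA"


def weighted_seq(pool: str, length: int) -> str:
    return "".join(pool[i] for i in RNG.integers(0, len(pool), size=length))


def subgroup_i_core(length: int, n_basic: int, n_trp: int, terminal: str) -> str:
    core = list(weighted_seq(SUBGROUP_I_CORE_POOL, length))
    slots = RNG.choice(length - 1, size=n_basic + n_trp, replace=False)
    for s in slots[:n_basic]:
        core[s] = "KR"[RNG.integers(2)]
    for s in slots[n_basic:]:
        core[s] = "W"
    core[-1] = terminal
    return "".join(core)


def subgroup_ii_core(length: int) -> str:
    core = list(weighted_seq(NEUTRAL_POOL, length))
    for s in RNG.choice(length - 1, size=2, replace=False):
        core[s] = "W"
    core[-1] = "A"
    return "".join(core)


def leader(length: int, asparaginyl: bool = False) -> str:
    pool = "ASTGLIVKEDNQ"
    seq = "M" + weighted_seq(pool, length - 1) if length > 1 else "M"
    if asparaginyl:
        seq = seq[:-1] + "N" if length > 1 else "N"
    return seq


def mutate_constrained(seq: str, identity_pct: float, allowed: str,
                       frozen: set[int] = frozenset()) -> str:
    """Substitute toward a target identity using only ``allowed``
    replacement residues, never touching ``frozen`` positions."""
    L = len(seq)
    k = int(round(L * (1.0 - identity_pct / 100.0)))
    positions = [i for i in range(L) if i not in frozen]
    chosen = RNG.choice(len(positions), size=min(k, len(positions)), replace=False)
    out = list(seq)
    for ci in chosen:
        pos = positions[ci]
        options = [a for a in allowed if a != out[pos]]
        out[pos] = options[RNG.integers(len(options))]
    return "".join(out)


# name -> (subgroup, leader_len, core builder args)
SUBGROUP_I_SINGLES = {
    "uberolysin": (6, 70),
    "carnocyclin A": (4, 60),
    "garvicin ML": (3, 60),
    "aureocyclicin 4185": (5, 61),
    "leucocyclicin Q": (2, 61),
}


def build_precursors() -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Returns [(name, subgroup, precursor_seq)], {name: leader_len}."""
    precursors: list[tuple[str, str, str]] = []
    leaders: dict[str, int] = {}

    def add(name: str, sub: str, lead: str, core: str) -> None:
        precursors.append((name, sub, lead + core))
        leaders[name] = len(lead)

    # family: amylocyclicin / amylocyclicin CMW1 / enterocin NKR-5-3B
    anc_core = subgroup_i_core(64, n_basic=6, n_trp=2, terminal="W")
    basic_pos = {i for i, a in enumerate(anc_core) if a in "KR"} | {63}
    add("amylocyclicin", "i", leader(9), anc_core)
    add("amylocyclicin CMW1", "i",
        leader(9), mutate_constrained(anc_core, 80, SUBGROUP_I_CORE_POOL, basic_pos))
    add("enterocin NKR-5-3B", "i",
        leader(24), mutate_constrained(anc_core, 70, SUBGROUP_I_CORE_POOL, basic_pos))

    # family: enterocin AS-48 / pumilarin / BacA
    anc_core = subgroup_i_core(70, n_basic=6, n_trp=3, terminal="W")
    basic_pos = {i for i, a in enumerate(anc_core) if a in "KR"} | {69}
    anc_lead = leader(35)
    add("enterocin AS-48", "i", anc_lead, anc_core)
    add("pumilarin", "i",
        mutate_constrained(anc_lead, 75, "ASTGLIVNQ", {0})[:32],
        mutate_constrained(anc_core, 75, SUBGROUP_I_CORE_POOL, basic_pos))
    add("BacA", "i",
        mutate_constrained(anc_lead, 70, "ASTGLIVNQ", {0})[:30],
        mutate_constrained(anc_core, 70, SUBGROUP_I_CORE_POOL, basic_pos))

    # circularin A == thermocin 485 (identical peptides)
    circ_core = subgroup_i_core(69, n_basic=5, n_trp=2, terminal="Y")
    circ_lead = leader(3)
    add("circularin A", "i", circ_lead, circ_core)
    add("thermocin 485", "i", circ_lead, circ_core)

    # remaining subgroup i members: unrelated families
    for name, (lead_len, core_len) in SUBGROUP_I_SINGLES.items():
        add(name, "i", leader(lead_len),
            subgroup_i_core(core_len, n_basic=RNG.integers(4, 7), n_trp=2,
                            terminal="WY"[RNG.integers(2)]))

    # the six subgroup ii bacteriocins: one family, asparaginyl cleavage,
    # neutral hydrophobic cores ending in alanine
    anc_core = subgroup_ii_core(58)
    anc_lead = leader(33, asparaginyl=True)
    ii_members = [
        ("acidocin B", 33), ("gassericin A", 33), ("butyrovibriocin AR10", 22),
        ("plantaricyclin A", 33), ("plantacyclin B21AG", 33), ("paracyclicin", 25),
    ]
    for name, lead_len in ii_members:
        core = mutate_constrained(anc_core, 82, NEUTRAL_POOL, {57})
        lead = mutate_constrained(anc_lead, 80, "ASTGLIVQ", {0, 32})
        lead = lead[-lead_len:] if lead_len < 33 else lead
        lead = ("M" + lead[1:-1] + "N") if len(lead) > 1 else "N"
        add(name, "ii", lead, core)

    return precursors, leaders


def build_supporting(names_subgroups: list[tuple[str, str]]) -> list[tuple[str, str, str, str]]:
    """[(name, role, subgroup, seq)] for transporter/spoIIM/accessories."""
    out = []
    transporter_anc = "M" + weighted_seq("AGLIVFSTMKRNDEQPWY", 219)
    spoiim_anc = "M" + weighted_seq("AGLIVFSTMKRNQWY", 169)
    for name, sub in names_subgroups:
        out.append((name, "transporter", sub,
                    mutate_to_identity(transporter_anc, 70.0, RNG)))
        out.append((name, "spoIIM", sub,
                    mutate_to_identity(spoiim_anc, 75.0, RNG)))
    out.append(("yip1 family", "yip1", "unknown",
                "M" + weighted_seq("AGLIVFSTMWY", 149)))
    out.append(("M48 peptidase", "peptidase", "unknown",
                "M" + weighted_seq("AGLIVFSTMKRNDEQHWY", 249)))
    out.append(("M50 peptidase", "peptidase", "unknown",
                "M" + weighted_seq("AGLIVFSTMKRNDEQHWY", 219)))
    return out


def main() -> None:
    data_dir = os.path.join(os.path.dirname(__file__), "..", "src", "cyclomine", "data")
    os.makedirs(data_dir, exist_ok=True)

    precursors, leaders = build_precursors()
    rows = []
    records = []

    def slug(name: str) -> str:
        return name.replace(" ", "_").replace("-", "_")

    for name, sub, seq in precursors:
        sid = f"{slug(name)}_precursor"
        records.append(ProteinRecord(id=sid, sequence=seq,
                                     description=f"synthetic stand-in precursor | {name}"))
        rows.append((sid, name, "precursor", sub))

    for name, role, sub, seq in build_supporting([(n, s) for n, s, _ in precursors]):
        sid = f"{slug(name)}_{role}"
        records.append(ProteinRecord(id=sid, sequence=seq,
                                     description=f"synthetic stand-in {role} | {name}"))
        rows.append((sid, name, role, sub))

    write_protein_fasta(records, os.path.join(data_dir, "seeds_synthetic.faa"))
    with open(os.path.join(data_dir, "seed_roles_synthetic.tsv"), "w") as fh:
        fh.write("seq_id\tbacteriocin_name\trole\tsubgroup\n")
        for sid, name, role, sub in rows:
            fh.write(f"{sid}\t{name}\t{role}\t{sub}\n")
    with open(os.path.join(data_dir, "cleavage_sites_synthetic.tsv"), "w") as fh:
        fh.write("bacteriocin_name\tleader_length\n")
        for name, lead_len in sorted(leaders.items()):
            fh.write(f"{name}\t{lead_len}\n")
    print(f"wrote {len(records)} seed records for {len(precursors)} bacteriocins")


if __name__ == "__main__":
    main()
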
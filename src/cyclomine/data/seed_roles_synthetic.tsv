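seq_id	bacteriocin_name	role	subgroup
amylocyclicin_precursor	amylocyclicin	precursor	i
amylocyclicin_CMW1_precursor	amylocyclicin CMW1	precursor	i
enterocin_NKR_5_3B_precursor	enterocin NKR-5-3B	precursor	i
enterocin_AS_48_precursor	enterocin AS-48	precursor	i
pumilarin_precursor	pumilarin	precursor	i
BacA_precursor	BacA	precursor	i
circularin_A_precursor	circularin A	precursor	i
thermocin_485_precursor	thermocin 485	precursor	i
uberolysin_precursor	uberolysin	precursor	i
carnocyclin_A_precursor	carnocyclin A	precursor	i
garvicin_ML_precursor	garvicin ML	precursor	i
aureocyclicin_4185_precursor	aureocyclicin 4185	precursor	i
leucocyclicin_Q_precursor	leucocyclicin Q	precursor	i
acidocin_B_precursor	acidocin B	precursor	ii
gassericin_A_precursor	gassericin A	precursor	ii
butyrovibriocin_AR10_precursor	butyrovibriocin AR10	precursor	ii
plantaricyclin_A_precursor	plantaricyclin A	precursor	ii
plantacyclin_B21AG_precursor	plantacyclin B21AG	precursor	ii
paracyclicin_precursor	paracyclicin	precursor	ii
amylocyclicin_transporter	amylocyclicin	transporter	i
amylocyclicin_spoIIM	amylocyclicin	spoIIM	i
amylocyclicin_CMW1_transporter	amylocyclicin CMW1	transporter	i
amylocyclicin_CMW1_spoIIM	amylocyclicin CMW1	spoIIM	i
enterocin_NKR_5_3B_transporter	enterocin NKR-5-3B	transporter	i
enterocin_NKR_5_3B_spoIIM	enterocin NKR-5-3B	spoIIM	i
enterocin_AS_48_transporter	enterocin AS-48	transporter	i
enterocin_AS_48_spoIIM	enterocin AS-48	spoIIM	i
pumilarin_transporter	pumilarin	transporter	i
pumilarin_spoIIM	pumilarin	spoIIM	i
BacA_transporter	BacA	transporter	i
BacA_spoIIM	BacA	spoIIM	i
circularin_A_transporter	circularin A	transporter	i
circularin_A_spoIIM	circularin A	spoIIM	i
thermocin_485_transporter	thermocin 485	transporter	i
thermocin_485_spoIIM	thermocin 485	spoIIM	i
uberolysin_transporter	uberolysin	transporter	i
uberolysin_spoIIM	uberolysin	spoIIM	i
carnocyclin_A_transporter	carnocyclin A	transporter	i
carnocyclin_A_spoIIM	carnocyclin A	spoIIM	i
garvicin_ML_transporter	garvicin ML	transporter	i
garvicin_ML_spoIIM	garvicin ML	spoIIM	i
aureocyclicin_4185_transporter	aureocyclicin 4185	transporter	i
aureocyclicin_4185_spoIIM	aureocyclicin 4185	spoIIM	i
leucocyclicin_Q_transporter	leucocyclicin Q	transporter	i
leucocyclicin_Q_spoIIM	leucocyclicin Q	spoIIM	i
acidocin_B_transporter	acidocin B	transporter	ii
acidocin_B_spoIIM	acidocin B	spoIIM	ii
gassericin_A_transporter	gassericin A	transporter	ii
gassericin_A_spoIIM	gassericin A	spoIIM	ii
butyrovibriocin_AR10_transporter	butyrovibriocin AR10	transporter	ii
butyrovibriocin_AR10_spoIIM	butyrovibriocin AR10	spoIIM	ii
plantaricyclin_A_transporter	plantaricyclin A	transporter	ii
plantaricyclin_A_spoIIM	plantaricyclin A	spoIIM	ii
plantacyclin_B21AG_transporter	plantacyclin B21AG	transporter	ii
plantacyclin_B21AG_spoIIM	plantacyclin B21AG	spoIIM	ii
paracyclicin_transporter	paracyclicin	transporter	ii
paracyclicin_spoIIM	paracyclicin	spoIIM	ii
yip1_family_yip1	yip1 family	yip1	unknown
M48_peptidase_peptidase	M48 peptidase	peptidase	unknown
M50_peptidase_peptidase	M50 peptidase	peptidase	unknown
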
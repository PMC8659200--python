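bacteriocin_name	leader_length
BacA	30
acidocin B	33
amylocyclicin	9
amylocyclicin CMW1	9
aureocyclicin 4185	5
butyrovibriocin AR10	22
carnocyclin A	4
circularin A	3
enterocin AS-48	35
enterocin NKR-5-3B	24
garvicin ML	3
gassericin A	33
leucocyclicin Q	2
paracyclicin	25
plantacyclin B21AG	33
plantaricyclin A	33
pumilarin	32
thermocin 485	3
uberolysin	6
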
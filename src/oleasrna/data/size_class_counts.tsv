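library	length	total	unique
juvenile	21	913	526
juvenile	22	1398	1041
juvenile	24	85428	57644
adult	21	494	361
adult	22	784	621
adult	24	52008	38352
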
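mutant	drug	log10_fold_change	expectation
E571K	vosaroxin	2.0	resistant
A652T	vosaroxin	2.0	resistant
L926F	vosaroxin	2.1	resistant
G474A/V475M	vosaroxin	4.0	resistant
G551S	vosaroxin	4.1	resistant
I636M	vosaroxin	4.0	resistant
S654N	vosaroxin	4.3	resistant
P716H	vosaroxin	4.5	resistant
P716T	vosaroxin	4.2	resistant
Q726H	vosaroxin	4.0	resistant
T858S	vosaroxin	4.1	resistant
L531F	vosaroxin	4.0	resistant
A748V	vosaroxin	4.2	resistant
V197M	ciprofloxacin	3.0	resistant
A484V	ciprofloxacin	2.8	resistant
S9F	ciprofloxacin	3.2	resistant
L148F	ciprofloxacin	2.5	resistant
A484T	ciprofloxacin	2.7	resistant
A457T	ciprofloxacin	3.3	resistant
G737D	ciprofloxacin	2.9	resistant
A725E	ciprofloxacin	2.6	resistant
E430K	ciprofloxacin	3.0	resistant
A830V	ciprofloxacin	0.2	resistant
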
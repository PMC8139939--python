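#NEXUS
[ five-split incompatible system on taxa {1..5}: 2-compatible, kappa = 3 ]

BEGIN TAXA;
DIMENSIONS NTAX=5;
TAXLABELS
    1
    2
    3
    4
    5
;
END;

BEGIN SPLITS;
DIMENSIONS NTAX=5 NSPLITS=5;
FORMAT labels=no weights=yes confidences=no;
CYCLE 1 2 3 4 5;
MATRIX
[1]	1.0	1 2,
[2]	1.0	2 3,
[3]	1.0	3 4,
[4]	1.0	4 5,
[5]	1.0	1 5,
;
END;
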
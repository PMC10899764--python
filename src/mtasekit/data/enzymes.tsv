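#name	motif	cut_offset	rules	note
Alw44I	GTGCAC	1	6:top,1:bottom|any	does not cut if the 3' cytosine is 5mC on at least one strand
XmiI	GTMKAC	2	6:top,1:bottom|both	blocked only when the 3' cytosine is 5mC on both strands
BsuRI	GGCC	2	3:top,2:bottom|any	blocked if the inner cytosine is 5mC on at least one strand
Bsh1236I	CGCG	2	1:top,3:top,2:bottom,4:bottom|any	blocked by hemimethylation of either cytosine
Hin6I	GCGC	1	2:top,3:bottom|both	does not cut if the site is 5mC-methylated on both strands
Eco47I	GGWCC	1	5:top,1:bottom|any;4:top,2:bottom|any	hemimethylation of the 3' cytosine blocks; 5mC at the inner cytosine also blocks
MspI	CCGG	1	1:top,4:bottom|any	one-strand 5mC of the outer cytosine suffices to block
BamHI	GGATCC	1	5:top,6:top,1:bottom,2:bottom|any	one-strand 5mC of any site cytosine suffices to block
NcoI	CCATGG	1	1:top,2:top,5:bottom,6:bottom|any	one-strand 5mC of any site cytosine suffices to block
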
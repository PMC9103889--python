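pdb_code	chain	protein_name
1ZUA	X	Aldo-keto reductase family 1 member B10
1E0X	A	Endo-1,4-beta-xylanase A precursor
1BK9		Phospholipase A2, acidic
1TU6	A	Cathepsin K precursor
1W4P	A	Ribonuclease pancreatic precursor
1JZF	A	Azurin precursor
1YMS	A	beta-lactamase CTX-M-9a
2WEA		Penicillopepsin
1HEE	A	Carboxypeptidase A1 precursor
1WBI	A	Avidin-related protein 2 precursor
1CXV	A	Collagenase 3 precursor
1H4G	A	Glycoside hydrolase
1TT1	A	Glutamate receptor, ionotropic kainate 2 precursor
2CYB	A	Tyrosyl-tRNA synthetase
1H60	A	Pentaerythritol tetranitrate reductase
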
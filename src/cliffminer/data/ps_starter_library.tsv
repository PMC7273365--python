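# Synthetic stand-in privileged-substructure library.
# Common privileged cores from the medicinal-chemistry literature; this file
# is a starter set, not a curated reference — replace it with your own
# pattern collection for production analyses.
# Format: NAME<TAB>SMARTS (SMILES accepted); '#' starts a comment line.
indole	c1ccc2[nH]ccc2c1
quinoline	c1ccc2ncccc2c1
isoquinoline	c1ccc2cnccc2c1
quinazoline	c1ccc2ncncc2c1
benzimidazole	c1ccc2[nH]cnc2c1
indazole	c1ccc2[nH]ncc2c1
benzofuran	c1ccc2occc2c1
benzothiophene	c1ccc2sccc2c1
carbazole	c1ccc2c(c1)[nH]c1ccccc12
biphenyl	c1ccc(-c2ccccc2)cc1
diphenylmethane	C(c1ccccc1)c1ccccc1
phenylpiperazine	C1CN(c2ccccc2)CCN1
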
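pathway	loci	n_snps	snps
Apoptosis	1;32;64	4	rs201089181;rs7542354;rs12203592;rs7226979
Apoptotic signalling pathway	1;32;64	4	rs201089181;rs7542354;rs12203592;rs7226979
Integrated pancreatic cancer pathway	1;37;64;66	6	rs201089181;rs7542354;rs9692245;rs62433864;rs7226979;rs17265513
Apoptosis modulation and signalling	1;54;64	4	rs201089181;rs7542354;rs417054;rs7226979
HIV-1 Nef: Negative effector of Fas and TNF-alpha	1;64	3	rs201089181;rs7542354;rs7226979
Caspase cascade in apoptosis	1;64;66	4	rs201089181;rs7542354;rs7226979;rs17265513
Prostate cancer - Homo sapiens (human)	12;37;64;71	11	rs534855217;rs191212334;rs577845405;rs534591951;rs13021718;rs9692245;rs62433864;rs7226979;rs4827528;rs113436165;rs7061504
Proteoglycans in cancer - Homo sapiens (human)	19;21;38;57;60	9	rs7349332;rs11684254;rs550618068;rs71530654;rs10225279;rs111931356;17_43947866;rs919462;rs572756998
ESC pluripotency pathways	19;27;37;60	7	rs7349332;rs7680591;rs9692245;rs62433864;17_43947866;rs919462;rs572756998
Pathways in cancer - Homo sapiens (human)	19;27;37;60;64;68;71	12	rs7349332;rs7680591;rs9692245;rs62433864;17_43947866;rs919462;rs572756998;rs7226979;rs68088846;rs4827528;rs113436165;rs7061504
Class B/2 (Secretin family receptors)	19;51;60	5	rs7349332;rs10843003;17_43947866;rs919462;rs572756998
Wnt signalling pathway	19;54;60	5	rs7349332;rs417054;17_43947866;rs919462;rs572756998
Wnt signalling pathway and pluripotency	19;54;60	5	rs7349332;rs417054;17_43947866;rs919462;rs572756998
WNT ligand biogenesis and trafficking	19;60	4	rs7349332;17_43947866;rs919462;rs572756998
Wnt signalling in kidney disease	19;60	4	rs7349332;17_43947866;rs919462;rs572756998
DNA damage response (only ATM dependent)	19;60;64	5	rs7349332;17_43947866;rs919462;rs572756998;rs7226979
Endochondral ossification	2;25;34;51	7	rs16830188;rs11249243;rs9803723;rs2064251;rs11714208;rs70993471;rs10843003
Regulation of nuclear SMAD2/3 signalling	2;34;68;71	9	rs16830188;rs11249243;rs9803723;rs2064251;rs70993471;rs68088846;rs4827528;rs113436165;rs7061504
TGF_beta_Receptor	2;34;68;71	9	rs16830188;rs11249243;rs9803723;rs2064251;rs70993471;rs68088846;rs4827528;rs113436165;rs7061504
Transcriptional misregulation in cancer - Homo sapiens (human)	20;34;37;68	5	rs77177529;rs70993471;rs9692245;rs62433864;rs68088846
Activation of the TFAP2 (AP-2) family of transcription factors	3;67	3	rs16827770;rs551865390;rs985546
White fat cell differentiation	31;32	2	rs1422798;rs12203592
Development of pulmonary dendritic cells and macrophage subsets	32;34	2	rs12203592;rs70993471
Notch-mediated HES/HEY network	34;38;71	6	rs70993471;rs71530654;rs10225279;rs4827528;rs113436165;rs7061504
Regulation of FZD by ubiquitination	42;48	6	rs182973285;rs16877149;rs77767830;rs79593277;rs530010717;rs79811440
Regulation of apoptosis by parathyroid hormone-related protein	51;64	2	rs10843003;rs7226979
Signalling by Wnt	9;19;29;42;48;60	13	rs78448052;rs7349332;rs73837363;rs76067940;rs182973285;rs16877149;rs77767830;rs79593277;rs530010717;rs79811440;17_43947866;rs919462;rs572756998
TCF-dependent signalling in response to WNT	9;29;42;48;60	12	rs78448052;rs73837363;rs76067940;rs182973285;rs16877149;rs77767830;rs79593277;rs530010717;rs79811440;17_43947866;rs919462;rs572756998
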
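drug_subclass	bnf_code	gene	chrom	start	end	mechanism
Calcium channel blockers	206020	CACNB2	10	18429606	18830688	calcium channel antagonist
Potassium-sparing diuretics and aldosterone antagonists	202030	SCNN1D	1	1215816	1227409	epithelial sodium channel blocker
Vasodilator antihypertensive drugs	205010	EDNRA	4	148402069	148466132	endothelin receptor antagonist
Vasodilator antihypertensive drugs	205010	KCNJ11	11	17406795	17410878	potassium channel opener
Beta-adrenoceptor blocking drugs	2040	ADRB1	10	115803625	115806673	beta-1 adrenoceptor antagonist
Angiotensin II receptor antagonists	205052	AGTR1	3	148415658	148460790	angiotensin II receptor antagonist
Angiotensin-converting enzyme inhibitors	205051	ACE	17	61554422	61599205	angiotensin-converting enzyme inhibitor
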
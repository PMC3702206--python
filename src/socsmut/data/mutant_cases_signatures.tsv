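case_id	age	sex	morphology	cd10	bcl2	bcl6_ihc	mum1	ki67	myc_fish	bcl6_fish	t14_18	coo	mbl	pap	cc
MPI-135	77	F	ANA	-	+	+	+	99	-	-	-	ABC	non-mBL	PAP-3	BCR
MPI-202	72	M	NOS	-	-	+	+	80	-	+	-	GCB	non-mBL	PAP-1	HR
MPI-166	54	M	NOS	+	+	+	+	30	-	-	+	GCB	non-mBL	mind-L	BCR
MPI-247	70	M	CB	-	+	+	+	90	-	+	-	unclassified	non-mBL	PAP-1	BCR
MPI-030	59	M	CB	-	+	+	+	60	-	-	-	GCB	non-mBL	PAP-1	HR
MPI-165	86	F	NOS	-	-	+	-	95	nIG	+	-	GCB	intermediate	mind-L	BCR
MPI-199	66	M	CB	-	+	+	+	50	-	-	-	ABC	non-mBL	PAP-1	HR
MPI-063	73	F	NOS	-	+	+	+	.	-	.	-	unclassified	non-mBL	PAP-3	OxPhos
MPI-092	58	F	CB	-	+	+	+	65	-	-	-	GCB	non-mBL	mind-L	OxPhos
MPI-157	40	M	NOS	-	+	+	-	45	-	+	-	unclassified	non-mBL	PAP-2	.
MPI-046	59	F	NOS	+	+	+	-	80	nIG	-	+	GCB	intermediate	PAP-3	BCR
MPI-134	29	F	CB	-	-	+	+	85	-	-	-	GCB	non-mBL	PAP-1	HR
MPI-105	60	F	CB	-	+	+	-	75	-	+	-	GCB	non-mBL	PAP-1	HR
MPI-241	40	F	NOS	-	+	+	-	80	-	+	-	GCB	non-mBL	mind-L	BCR
MPI-122	18	M	CB	-	+	+	+	90	-	-	-	GCB	non-mBL	PAP-1	HR
MPI-220	65	F	NOS	+	+	+	.	90	IG	-	-	GCB	mBL	mind-L	.
MPI-248	56	M	IB	+	+	+	-	50	nIG	-	+	GCB	intermediate	mind-L	BCR
MPI-136	32	M	CB	-	+	+	-	95	-	-	-	GCB	non-mBL	PAP-1	HR
MPI-137	18	M	NOS	-	+	+	+	85	-	-	-	GCB	non-mBL	PAP-1	.
MPI-207	27	M	NOS	-	-	+	+	70	-	-	-	GCB	non-mBL	PAP-1	HR
MPI-036	70	F	CB	+	+	+	-	98	IG	-	+	GCB	intermediate	mind-L	BCR
MPI-153	78	F	CB	-	-	.	.	50	-	+	-	GCB	non-mBL	PAP-1	BCR
MPI-102	21	F	NOS	+	+	+	-	80	nIG	-	-	GCB	non-mBL	PAP-1	.
MPI-109	42	M	CB	+	-	+	-	75	-	-	-	GCB	non-mBL	PAP-4	BCR
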
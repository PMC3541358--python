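cne_id	domain	mt	zt	mg	zg
Hs259	limbs	+	-	+	-
Hs259	spinal cord	-	+	+	+
Hs327	hindbrain	+	+	+	+
Hs327	forebrain	-	+	+	+
Hs327	spinal cord	+	+	+	-
Hs327	midbrain	-	+	+	+
Hs382	forebrain	+	+	+	+
Hs382	somites	+	+	+	+
Hs382	spinal cord	+	-	+	+
Hs382	DRG	+	-	+	-
Hs382	eye	-	+	+	+
Hs382	notochord	-	+	+	+
Hs382	hindbrain	+	-	+	+
Hs382	midbrain	+	-	+	+
Hs422	forebrain	+	+	+	+
Hs422	spinal cord	-	+	-	-
Hs422	nose	+	-	+	-
Hs422	hindbrain	-	+	-	-
Hs595	forebrain	+	+	+	+
Hs595	midbrain	+	-	+	+
Hs595	nose	+	-	+	-
Hs609	forebrain	+	-	+	+
Hs609	limbs	+	-	+	-
Hs671	forebrain	+	+	+	+
Hs671	eye	-	+	+	+
Hs671	hindbrain	-	+	+	+
Hs671	DRG	-	+	+	-
Hs672	forebrain	+	-	+	+
Hs672	midbrain	+	+	+	+
Hs672	spinal cord	+	-	+	-
Hs687	forebrain	+	+	+	+
Hs687	spinal cord	+	-	+	-
Hs774	hindbrain	+	+	+	+
Hs774	limbs	+	+	+	-
Hs774	forebrain	-	+	+	+
Hs774	eye	-	+	-	+
Hs1114	midbrain	+	+	+	+
Hs1114	hindbrain	+	+	-	+
Hs1114	spinal cord	+	+	+	+
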
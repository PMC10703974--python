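# Ionizable-group SMARTS patterns for salt-bridge detection on docked ligands.
# Format: sign <TAB> SMARTS ; the FIRST atom of each pattern is the charged atom.
# Formal charges are often unreliable after docking, so neutral protonatable /
# deprotonatable forms are matched alongside explicitly charged atoms.
# Cations ----------------------------------------------------------------
+	[NX4+]
+	[NX3+;!$([NX3+]-[O-])]
+	[NX3;H2;+0;!$(NC=[O,S,N]);!$(N[a]);!$(N~[!#6;!#1])][CX4]
+	[NX3;H1;+0;!$(NC=[O,S,N]);!$(N[a]);!$(N~[!#6;!#1])]([CX4])[CX4]
+	[NX3;H0;+0;!$(NC=[O,S,N]);!$(N[a]);!$(N~[!#6;!#1]);!$(N=*)]([CX4])([CX4])[CX4]
# guanidinium / amidinium nitrogens (either resonance form)
+	[NX3;!$(N[a])][CX3]=[NX2;!$(N[a])]
+	[NX2;!$(N[a])]=[CX3][NX3;!$(N[a])]
# Anions -----------------------------------------------------------------
-	[O-]
-	[OX1]=[CX3][OX2H1,OX1-]
-	[OX2H1][CX3]=[OX1]
-	[OX1,OX2H1;$(O[PX4]=O)]
-	[OX1,OX2H1;$(O[SX4](=O)=O)]
# tetrazole ring nitrogens (acidic NH or deprotonated)
-	[n-]
-	[n;!$([n-]);$(n1nnnc1),$(n1nncn1)]
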
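# Default ico-1 patch -> anatomical region mapping (synthetic reconstruction).
# The 11-per-hemisphere anatomical grouping of Desikan-Killiany labels is not
# published as a table; this file is a plausible reconstruction in which only the
# frontoparietal (fpc) membership -- precentral, postcentral, paracentral -- and
# the medial temporal labels are constrained. Override with any file of the same
# schema to use a different grouping.
patch_id	hemisphere	dk_label	region
L00	left	precentral	fpc
L01	left	precentral	fpc
L02	left	precentral	fpc
L03	left	postcentral	fpc
L04	left	postcentral	fpc
L05	left	paracentral	fpc
L06	left	superiorfrontal	dorsolateral_prefrontal
L07	left	superiorfrontal	dorsolateral_prefrontal
L08	left	superiorfrontal	dorsolateral_prefrontal
L09	left	rostralmiddlefrontal	dorsolateral_prefrontal
L10	left	rostralmiddlefrontal	dorsolateral_prefrontal
L11	left	caudalmiddlefrontal	dorsolateral_prefrontal
L12	left	parsopercularis	inferior_frontal
L13	left	parstriangularis	inferior_frontal
L14	left	parsorbitalis	inferior_frontal
L15	left	lateralorbitofrontal	orbitofrontal
L16	left	medialorbitofrontal	orbitofrontal
L17	left	frontalpole	orbitofrontal
L18	left	rostralanteriorcingulate	cingulate
L19	left	caudalanteriorcingulate	cingulate
L20	left	posteriorcingulate	cingulate
L21	left	isthmuscingulate	cingulate
L22	left	superiorparietal	superior_parietal
L23	left	superiorparietal	superior_parietal
L24	left	precuneus	superior_parietal
L25	left	precuneus	superior_parietal
L26	left	inferiorparietal	inferior_parietal
L27	left	inferiorparietal	inferior_parietal
L28	left	supramarginal	inferior_parietal
L29	left	supramarginal	inferior_parietal
L30	left	superiortemporal	lateral_temporal
L31	left	superiortemporal	lateral_temporal
L32	left	middletemporal	lateral_temporal
L33	left	inferiortemporal	lateral_temporal
L34	left	bankssts	lateral_temporal
L35	left	parahippocampal	medial_temporal
L36	left	entorhinal	medial_temporal
L37	left	fusiform	medial_temporal
L38	left	lateraloccipital	occipital
L39	left	cuneus	occipital
L40	left	pericalcarine	occipital
L41	left	insula	insula
R00	right	precentral	fpc
R01	right	precentral	fpc
R02	right	precentral	fpc
R03	right	postcentral	fpc
R04	right	postcentral	fpc
R05	right	paracentral	fpc
R06	right	superiorfrontal	dorsolateral_prefrontal
R07	right	superiorfrontal	dorsolateral_prefrontal
R08	right	superiorfrontal	dorsolateral_prefrontal
R09	right	rostralmiddlefrontal	dorsolateral_prefrontal
R10	right	rostralmiddlefrontal	dorsolateral_prefrontal
R11	right	caudalmiddlefrontal	dorsolateral_prefrontal
R12	right	parsopercularis	inferior_frontal
R13	right	parstriangularis	inferior_frontal
R14	right	parsorbitalis	inferior_frontal
R15	right	lateralorbitofrontal	orbitofrontal
R16	right	medialorbitofrontal	orbitofrontal
R17	right	frontalpole	orbitofrontal
R18	right	rostralanteriorcingulate	cingulate
R19	right	caudalanteriorcingulate	cingulate
R20	right	posteriorcingulate	cingulate
R21	right	isthmuscingulate	cingulate
R22	right	superiorparietal	superior_parietal
R23	right	superiorparietal	superior_parietal
R24	right	precuneus	superior_parietal
R25	right	precuneus	superior_parietal
R26	right	inferiorparietal	inferior_parietal
R27	right	inferiorparietal	inferior_parietal
R28	right	supramarginal	inferior_parietal
R29	right	supramarginal	inferior_parietal
R30	right	superiortemporal	lateral_temporal
R31	right	superiortemporal	lateral_temporal
R32	right	middletemporal	lateral_temporal
R33	right	inferiortemporal	lateral_temporal
R34	right	bankssts	lateral_temporal
R35	right	parahippocampal	medial_temporal
R36	right	entorhinal	medial_temporal
R37	right	fusiform	medial_temporal
R38	right	lateraloccipital	occipital
R39	right	cuneus	occipital
R40	right	pericalcarine	occipital
R41	right	insula	insula
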
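label	x	y	z
ctx-lh-bankssts	-35	-75	-50
ctx-lh-caudalanteriorcingulate	-35	-50	-50
ctx-lh-caudalmiddlefrontal	-35	-25	-50
ctx-lh-cuneus	-35	0	-50
ctx-lh-entorhinal	-35	25	-50
ctx-lh-frontalpole	-35	50	-50
ctx-lh-fusiform	-35	75	-50
ctx-lh-inferiorparietal	-40	-75	-30
ctx-lh-inferiortemporal	-40	-50	-30
ctx-lh-insula	-40	-25	-30
ctx-lh-isthmuscingulate	-40	0	-30
ctx-lh-lateraloccipital	-40	25	-30
ctx-lh-lateralorbitofrontal	-40	50	-30
ctx-lh-lingual	-40	75	-30
ctx-lh-medialorbitofrontal	-35	-75	-10
ctx-lh-middletemporal	-35	-50	-10
ctx-lh-paracentral	-35	-25	-10
ctx-lh-parahippocampal	-35	0	-10
ctx-lh-parsopercularis	-35	25	-10
ctx-lh-parsorbitalis	-35	50	-10
ctx-lh-parstriangularis	-35	75	-10
ctx-lh-pericalcarine	-40	-75	10
ctx-lh-postcentral	-40	-50	10
ctx-lh-posteriorcingulate	-40	-25	10
ctx-lh-precentral	-40	0	10
ctx-lh-precuneus	-40	25	10
ctx-lh-rostralanteriorcingulate	-40	50	10
ctx-lh-rostralmiddlefrontal	-40	75	10
ctx-lh-superiorfrontal	-35	-75	30
ctx-lh-superiorparietal	-35	-50	30
ctx-lh-superiortemporal	-35	-25	30
ctx-lh-supramarginal	-35	0	30
ctx-lh-temporalpole	-35	25	30
ctx-lh-transversetemporal	-35	50	30
lh-thalamus	-35	75	30
lh-caudate	-40	-75	50
lh-putamen	-40	-50	50
lh-pallidum	-40	-25	50
lh-accumbens	-40	0	50
lh-hippocampus	-40	25	50
lh-amygdala	-40	50	50
lh-cerebellum	-40	75	50
ctx-rh-bankssts	35	-75	-50
ctx-rh-caudalanteriorcingulate	35	-50	-50
ctx-rh-caudalmiddlefrontal	35	-25	-50
ctx-rh-cuneus	35	0	-50
ctx-rh-entorhinal	35	25	-50
ctx-rh-frontalpole	35	50	-50
ctx-rh-fusiform	35	75	-50
ctx-rh-inferiorparietal	40	-75	-30
ctx-rh-inferiortemporal	40	-50	-30
ctx-rh-insula	40	-25	-30
ctx-rh-isthmuscingulate	40	0	-30
ctx-rh-lateraloccipital	40	25	-30
ctx-rh-lateralorbitofrontal	40	50	-30
ctx-rh-lingual	40	75	-30
ctx-rh-medialorbitofrontal	35	-75	-10
ctx-rh-middletemporal	35	-50	-10
ctx-rh-paracentral	35	-25	-10
ctx-rh-parahippocampal	35	0	-10
ctx-rh-parsopercularis	35	25	-10
ctx-rh-parsorbitalis	35	50	-10
ctx-rh-parstriangularis	35	75	-10
ctx-rh-pericalcarine	40	-75	10
ctx-rh-postcentral	40	-50	10
ctx-rh-posteriorcingulate	40	-25	10
ctx-rh-precentral	40	0	10
ctx-rh-precuneus	40	25	10
ctx-rh-rostralanteriorcingulate	40	50	10
ctx-rh-rostralmiddlefrontal	40	75	10
ctx-rh-superiorfrontal	35	-75	30
ctx-rh-superiorparietal	35	-50	30
ctx-rh-superiortemporal	35	-25	30
ctx-rh-supramarginal	35	0	30
ctx-rh-temporalpole	35	25	30
ctx-rh-transversetemporal	35	50	30
rh-thalamus	35	75	30
rh-caudate	40	-75	50
rh-putamen	40	-50	50
rh-pallidum	40	-25	50
rh-accumbens	40	0	50
rh-hippocampus	40	25	50
rh-amygdala	40	50	50
rh-cerebellum	40	75	50
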
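# Desikan-Killiany 68-region atlas: index -> region name and anatomical lobe.
# Indices 1-34 are left hemisphere, 35-68 right, both in FreeSurfer aparc order.
# Override with any YAML of the same shape via the lobe_map config/CLI option.
1: {name: lh-bankssts, lobe: temporal}
2: {name: lh-caudalanteriorcingulate, lobe: limbic}
3: {name: lh-caudalmiddlefrontal, lobe: frontal}
4: {name: lh-cuneus, lobe: occipital}
5: {name: lh-entorhinal, lobe: temporal}
6: {name: lh-fusiform, lobe: temporal}
7: {name: lh-inferiorparietal, lobe: parietal}
8: {name: lh-inferiortemporal, lobe: temporal}
9: {name: lh-isthmuscingulate, lobe: limbic}
10: {name: lh-lateraloccipital, lobe: occipital}
11: {name: lh-lateralorbitofrontal, lobe: frontal}
12: {name: lh-lingual, lobe: occipital}
13: {name: lh-medialorbitofrontal, lobe: frontal}
14: {name: lh-middletemporal, lobe: temporal}
15: {name: lh-parahippocampal, lobe: temporal}
16: {name: lh-paracentral, lobe: frontal}
17: {name: lh-parsopercularis, lobe: frontal}
18: {name: lh-parsorbitalis, lobe: frontal}
19: {name: lh-parstriangularis, lobe: frontal}
20: {name: lh-pericalcarine, lobe: occipital}
21: {name: lh-postcentral, lobe: parietal}
22: {name: lh-posteriorcingulate, lobe: limbic}
23: {name: lh-precentral, lobe: frontal}
24: {name: lh-precuneus, lobe: parietal}
25: {name: lh-rostralanteriorcingulate, lobe: limbic}
26: {name: lh-rostralmiddlefrontal, lobe: frontal}
27: {name: lh-superiorfrontal, lobe: frontal}
28: {name: lh-superiorparietal, lobe: parietal}
29: {name: lh-superiortemporal, lobe: temporal}
30: {name: lh-supramarginal, lobe: parietal}
31: {name: lh-frontalpole, lobe: frontal}
32: {name: lh-temporalpole, lobe: temporal}
33: {name: lh-transversetemporal, lobe: temporal}
34: {name: lh-insula, lobe: insular}
35: {name: rh-bankssts, lobe: temporal}
36: {name: rh-caudalanteriorcingulate, lobe: limbic}
37: {name: rh-caudalmiddlefrontal, lobe: frontal}
38: {name: rh-cuneus, lobe: occipital}
39: {name: rh-entorhinal, lobe: temporal}
40: {name: rh-fusiform, lobe: temporal}
41: {name: rh-inferiorparietal, lobe: parietal}
42: {name: rh-inferiortemporal, lobe: temporal}
43: {name: rh-isthmuscingulate, lobe: limbic}
44: {name: rh-lateraloccipital, lobe: occipital}
45: {name: rh-lateralorbitofrontal, lobe: frontal}
46: {name: rh-lingual, lobe: occipital}
47: {name: rh-medialorbitofrontal, lobe: frontal}
48: {name: rh-middletemporal, lobe: temporal}
49: {name: rh-parahippocampal, lobe: temporal}
50: {name: rh-paracentral, lobe: frontal}
51: {name: rh-parsopercularis, lobe: frontal}
52: {name: rh-parsorbitalis, lobe: frontal}
53: {name: rh-parstriangularis, lobe: frontal}
54: {name: rh-pericalcarine, lobe: occipital}
55: {name: rh-postcentral, lobe: parietal}
56: {name: rh-posteriorcingulate, lobe: limbic}
57: {name: rh-precentral, lobe: frontal}
58: {name: rh-precuneus, lobe: parietal}
59: {name: rh-rostralanteriorcingulate, lobe: limbic}
60: {name: rh-rostralmiddlefrontal, lobe: frontal}
61: {name: rh-superiorfrontal, lobe: frontal}
62: {name: rh-superiorparietal, lobe: parietal}
63: {name: rh-superiortemporal, lobe: temporal}
64: {name: rh-supramarginal, lobe: parietal}
65: {name: rh-frontalpole, lobe: frontal}
66: {name: rh-temporalpole, lobe: temporal}
67: {name: rh-transversetemporal, lobe: temporal}
68: {name: rh-insula, lobe: insular}
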
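# Meta-analytic PTSD regions mapped to Human Brainnetome Atlas labels.
# 17 regions covering 106 unique atlas labels; regions listed once even when
# they appear in both the hyper- and hypo-activation contrasts of the source
# meta-analysis (right cingulate gyrus, left insula).
atlas_name: brainnetome
regions:
  - name: rCG
    description: Right cingulate gyrus (substituted for dorsal anterior cingulate)
    labels: [176, 178, 180, 182, 184, 186, 188]
  - name: lIns
    description: Left insula
    labels: [163, 165, 167, 169, 171, 173]
  - name: rPreC
    description: Right precuneus
    labels: [148, 150, 152, 154]
  - name: lSTG
    description: Left superior temporal gyrus
    labels: [69, 71, 73, 75, 77, 79]
  - name: lITG
    description: Left inferior temporal gyrus
    labels: [89, 91, 93, 95, 97, 99, 101]
  - name: lFG
    description: Left fusiform gyrus
    labels: [103, 105, 107]
  - name: rThal
    description: Right thalamus
    labels: [232, 234, 236, 238, 240, 242, 244, 246]
  - name: rOFC
    description: Right orbitofrontal cortex
    labels: [42, 44, 46, 48, 50, 52]
  - name: rIFG
    description: Right inferior frontal gyrus
    labels: [30, 32, 34, 36, 38, 40]
  - name: rSFG
    description: Right medial/superior frontal gyrus
    labels: [2, 4, 6, 8, 10, 12, 14]
  - name: lOFG
    description: Left frontal pole (orbitofrontal gyrus)
    labels: [41, 43, 45, 47, 49, 51]
  - name: rPCG
    description: Right precentral gyrus
    labels: [54, 56, 58, 60, 62, 64]
  - name: rMFG
    description: Right middle frontal gyrus
    labels: [16, 18, 20, 22, 24, 26, 28]
  - name: lPHG
    description: Left parahippocampal gyrus
    labels: [109, 111, 113, 115, 117, 119]
  - name: lThal
    description: Left thalamus
    labels: [231, 233, 235, 237, 239, 241, 243, 245]
  - name: lIFG
    description: Left inferior frontal gyrus
    labels: [29, 31, 33, 35, 37, 39]
  - name: lMFG
    description: Left middle frontal gyrus
    labels: [15, 17, 19, 21, 23, 25, 27]
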
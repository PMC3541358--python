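# Major anatomical domains used for mouse/zebrafish embryo comparison at
# the phylotypic stage (mouse 11.5 dpc, zebrafish 24-48 hpf).  Each entry
# names the canonical term and its per-species local term; a null species
# term means the domain has no homolog in that species and is excluded
# from cross-species comparison.
- name: forebrain
  mouse: forebrain
  zebrafish: forebrain
- name: midbrain
  mouse: midbrain
  zebrafish: midbrain
- name: hindbrain
  mouse: hindbrain
  zebrafish: hindbrain
- name: spinal cord
  mouse: spinal cord
  zebrafish: spinal cord
- name: DRG
  mouse: dorsal root ganglia
  zebrafish: dorsal root ganglia
- name: eye
  mouse: eye
  zebrafish: eye
- name: nose
  mouse: nose
  zebrafish: olfactory placode
- name: limbs
  mouse: limbs
  zebrafish: pectoral fins
- name: somites
  mouse: somites
  zebrafish: somites
- name: notochord
  mouse: notochord
  zebrafish: notochord
- name: heart
  mouse: heart
  zebrafish: heart
- name: otic vesicle
  mouse: otic vesicle
  zebrafish: otic vesicle
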
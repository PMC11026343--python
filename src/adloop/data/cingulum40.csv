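name,hemisphere,group,ap_class,braak_stage,abeta_seed,tau_seed
Left frontal pole,left,frontal,anterior,V,0,0
Left rostral middle frontal,left,frontal,anterior,V,0,0
Left caudal middle frontal,left,frontal,anterior,V,0,0
Left superior frontal,left,frontal,anterior,V,0,0
Left lateral orbitofrontal,left,frontal,anterior,V,1,0
Left medial orbitofrontal,left,frontal,anterior,V,1,0
Left insula,left,insula,excluded,IV,1,0
Left caudal anterior cingulate,left,anterior-cingulate,anterior,V,0,0
Left rostral anterior cingulate,left,anterior-cingulate,anterior,V,0,0
Left posterior cingulate,left,posterior-cingulate,posterior,IV,1,0
Left isthmus cingulate,left,posterior-cingulate,posterior,V,1,0
Left superior parietal,left,parietal,posterior,V,0,0
Left inferior parietal,left,parietal,posterior,IV,0,0
Left precuneus,left,parietal,posterior,V,1,0
Left inferior temporal,left,temporal,excluded,IV,0,0
Left parahippocampal,left,medial-temporal,excluded,III,0,0
Left hippocampus,left,medial-temporal,excluded,II,0,0
Left thalamus,left,subcortical,excluded,none,0,0
Left amygdala,left,medial-temporal,excluded,III,0,0
Left entorhinal cortex,left,medial-temporal,excluded,I,0,1
Right frontal pole,right,frontal,anterior,V,0,0
Right rostral middle frontal,right,frontal,anterior,V,0,0
Right caudal middle frontal,right,frontal,anterior,V,0,0
Right superior frontal,right,frontal,anterior,V,0,0
Right lateral orbitofrontal,right,frontal,anterior,V,1,0
Right medial orbitofrontal,right,frontal,anterior,V,1,0
Right insula,right,insula,excluded,IV,1,0
Right caudal anterior cingulate,right,anterior-cingulate,anterior,V,0,0
Right rostral anterior cingulate,right,anterior-cingulate,anterior,V,0,0
Right posterior cingulate,right,posterior-cingulate,posterior,IV,1,0
Right isthmus cingulate,right,posterior-cingulate,posterior,V,1,0
Right superior parietal,right,parietal,posterior,V,0,0
Right inferior parietal,right,parietal,posterior,IV,0,0
Right precuneus,right,parietal,posterior,V,1,0
Right inferior temporal,right,temporal,excluded,IV,0,0
Right parahippocampal,right,medial-temporal,excluded,III,0,0
Right hippocampus,right,medial-temporal,excluded,II,0,0
Right thalamus,right,subcortical,excluded,none,0,0
Right amygdala,right,medial-temporal,excluded,III,0,0
Right entorhinal cortex,right,medial-temporal,excluded,I,0,1
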
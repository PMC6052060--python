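strain1,strain2,predicted_didd,observed_didd,split
rodZ_del,WT,0.109,0.101,training
rodZ_del + rodZ,WT,-0.022,0.000,training
rodZ_del + rodZ_59-337,rodZ_del + rodZ,0.036,0.051,training
rodZ_del + rodZ_70-337,rodZ_del + rodZ,0.082,0.076,training
rodZ_del + rodZ_83-337,rodZ_del + rodZ,0.059,0.073,training
rodZ_del + rodZ_1-155,rodZ_del + rodZ,0.012,0.005,training
rodZ_del + rodZ_1-142,rodZ_del + rodZ,0.040,0.045,training
rodZ_del + rodZ_1-111,rodZ_del + rodZ,0.077,0.070,training
rodZ_del + pTrc99A,WT,0.071,0.098,training
rodZ_del + rodZ_59-337,rodZ_del + pTrc99A,-0.062,-0.047,training
rodZ_del + rodZ_70-337,rodZ_del + pTrc99A,-0.016,-0.022,training
rodZ_del + rodZ_83-337,rodZ_del + pTrc99A,-0.039,-0.025,training
rodZ_del + rodZ_1-155,rodZ_del + pTrc99A,-0.086,-0.093,training
rodZ_del + rodZ_1-142,rodZ_del + pTrc99A,-0.057,-0.053,training
rodZ_del + rodZ_1-111,rodZ_del + pTrc99A,-0.020,-0.028,training
MreB_S14A,WT,0.020,0.013,training
MreB_E143A,WT,0.017,0.007,training
MreB_Y183N,WT,0.075,0.120,training
MreB_S14A rodZ_del,MreB_S14A,0.028,0.012,training
MreB_E143A rodZ_del,MreB_E143A,0.072,0.053,training
MreB_E143A rodZ_del + pTrc99A,MreB_E143A rodZ_del + MreB_E143A,0.027,0.045,testing
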
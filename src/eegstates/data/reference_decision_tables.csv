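group,index,mod_a,mod_b,decision,borderline
Meditator,H,MED,MM,1,0
Meditator,H,MED,WORDS,1,0
Meditator,H,MED,SENT,0,0
Meditator,H,MED,IMG,1,0
Meditator,H,MED,VDO,1,0
Non-Meditator,H,MED,MM,1,0
Meditator,H,MM,WORDS,0,0
Meditator,H,MM,SENT,1,0
Meditator,H,MM,IMG,0,0
Meditator,H,MM,VDO,1,0
Non-Meditator,H,MED,WORDS,1,0
Non-Meditator,H,MM,WORDS,0,0
Meditator,H,WORDS,SENT,0,0
Meditator,H,WORDS,IMG,0,0
Meditator,H,WORDS,VDO,1,0
Non-Meditator,H,MED,SENT,0,0
Non-Meditator,H,MM,SENT,0,0
Non-Meditator,H,WORDS,SENT,0,0
Meditator,H,SENT,IMG,1,0
Meditator,H,SENT,VDO,1,0
Non-Meditator,H,MED,IMG,1,0
Non-Meditator,H,MM,IMG,0,0
Non-Meditator,H,WORDS,IMG,0,0
Non-Meditator,H,SENT,IMG,0,0
Meditator,H,IMG,VDO,1,0
Non-Meditator,H,MED,VDO,1,0
Non-Meditator,H,MM,VDO,0,0
Non-Meditator,H,WORDS,VDO,1,0
Non-Meditator,H,SENT,VDO,1,0
Non-Meditator,H,IMG,VDO,0,0
Meditator,PSk,MED,MM,1,0
Meditator,PSk,MED,WORDS,1,0
Meditator,PSk,MED,SENT,1,1
Meditator,PSk,MED,IMG,1,0
Meditator,PSk,MED,VDO,1,0
Non-Meditator,PSk,MED,MM,1,0
Meditator,PSk,MM,WORDS,0,0
Meditator,PSk,MM,SENT,1,0
Meditator,PSk,MM,IMG,0,0
Meditator,PSk,MM,VDO,1,0
Non-Meditator,PSk,MED,WORDS,1,0
Non-Meditator,PSk,MM,WORDS,0,0
Meditator,PSk,WORDS,SENT,1,0
Meditator,PSk,WORDS,IMG,0,0
Meditator,PSk,WORDS,VDO,1,0
Non-Meditator,PSk,MED,SENT,0,0
Non-Meditator,PSk,MM,SENT,0,0
Non-Meditator,PSk,WORDS,SENT,0,0
Meditator,PSk,SENT,IMG,1,0
Meditator,PSk,SENT,VDO,1,0
Non-Meditator,PSk,MED,IMG,1,0
Non-Meditator,PSk,MM,IMG,0,0
Non-Meditator,PSk,WORDS,IMG,0,0
Non-Meditator,PSk,SENT,IMG,1,0
Meditator,PSk,IMG,VDO,1,0
Non-Meditator,PSk,MED,VDO,1,0
Non-Meditator,PSk,MM,VDO,1,0
Non-Meditator,PSk,WORDS,VDO,1,0
Non-Meditator,PSk,SENT,VDO,1,0
Non-Meditator,PSk,IMG,VDO,0,0
Meditator,TP,MED,MM,1,0
Meditator,TP,MED,WORDS,1,0
Meditator,TP,MED,SENT,1,0
Meditator,TP,MED,IMG,1,0
Meditator,TP,MED,VDO,1,0
Non-Meditator,TP,MED,MM,0,0
Meditator,TP,MM,WORDS,0,0
Meditator,TP,MM,SENT,0,0
Meditator,TP,MM,IMG,0,0
Meditator,TP,MM,VDO,0,1
Non-Meditator,TP,MED,WORDS,0,0
Non-Meditator,TP,MM,WORDS,0,0
Meditator,TP,WORDS,SENT,0,0
Meditator,TP,WORDS,IMG,0,0
Meditator,TP,WORDS,VDO,1,0
Non-Meditator,TP,MED,SENT,0,0
Non-Meditator,TP,MM,SENT,0,0
Non-Meditator,TP,WORDS,SENT,0,0
Meditator,TP,SENT,IMG,1,0
Meditator,TP,SENT,VDO,1,0
Non-Meditator,TP,MED,IMG,0,0
Non-Meditator,TP,MM,IMG,0,0
Non-Meditator,TP,WORDS,IMG,1,0
Non-Meditator,TP,SENT,IMG,0,0
Meditator,TP,IMG,VDO,0,0
Non-Meditator,TP,MED,VDO,0,0
Non-Meditator,TP,MM,VDO,0,0
Non-Meditator,TP,WORDS,VDO,1,0
Non-Meditator,TP,SENT,VDO,0,0
Non-Meditator,TP,IMG,VDO,0,0
Meditator,DFs,MED,MM,1,0
Meditator,DFs,MED,WORDS,1,0
Meditator,DFs,MED,SENT,1,0
Meditator,DFs,MED,IMG,1,0
Meditator,DFs,MED,VDO,1,0
Non-Meditator,DFs,MED,MM,1,0
Meditator,DFs,MM,WORDS,0,0
Meditator,DFs,MM,SENT,0,0
Meditator,DFs,MM,IMG,0,0
Meditator,DFs,MM,VDO,0,0
Non-Meditator,DFs,MED,WORDS,1,0
Non-Meditator,DFs,MM,WORDS,0,0
Meditator,DFs,WORDS,SENT,0,0
Meditator,DFs,WORDS,IMG,0,0
Meditator,DFs,WORDS,VDO,1,0
Non-Meditator,DFs,MED,SENT,1,0
Non-Meditator,DFs,MM,SENT,0,0
Non-Meditator,DFs,WORDS,SENT,0,0
Meditator,DFs,SENT,IMG,0,0
Meditator,DFs,SENT,VDO,1,0
Non-Meditator,DFs,MED,IMG,1,0
Non-Meditator,DFs,MM,IMG,0,0
Non-Meditator,DFs,WORDS,IMG,0,0
Non-Meditator,DFs,SENT,IMG,0,0
Meditator,DFs,IMG,VDO,1,0
Non-Meditator,DFs,MED,VDO,1,0
Non-Meditator,DFs,MM,VDO,0,0
Non-Meditator,DFs,WORDS,VDO,1,0
Non-Meditator,DFs,SENT,VDO,0,0
Non-Meditator,DFs,IMG,VDO,0,0
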
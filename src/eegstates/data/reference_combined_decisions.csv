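group,mod_a,mod_b,category
Meditator,MED,MM,Reject
Meditator,MED,WORDS,Reject
Meditator,MED,SENT,Reject
Meditator,MED,IMG,Reject
Meditator,MED,VDO,Reject
Non-Meditator,MED,MM,Reject
Meditator,MM,WORDS,Accept
Meditator,MM,SENT,Neutral
Meditator,MM,IMG,Accept
Meditator,MM,VDO,Reject
Non-Meditator,MED,WORDS,Reject
Non-Meditator,MM,WORDS,Accept
Meditator,WORDS,SENT,Accept
Meditator,WORDS,IMG,Accept
Meditator,WORDS,VDO,Reject
Non-Meditator,MED,SENT,Accept
Non-Meditator,MM,SENT,Accept
Non-Meditator,WORDS,SENT,Accept
Meditator,SENT,IMG,Reject
Meditator,SENT,VDO,Reject
Non-Meditator,MED,IMG,Reject
Non-Meditator,MM,IMG,Accept
Non-Meditator,WORDS,IMG,Accept
Non-Meditator,SENT,IMG,Accept
Meditator,IMG,VDO,Reject
Non-Meditator,MED,VDO,Reject
Non-Meditator,MM,VDO,Accept
Non-Meditator,WORDS,VDO,Reject
Non-Meditator,SENT,VDO,Neutral
Non-Meditator,IMG,VDO,Accept
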
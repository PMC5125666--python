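label,duration_sec,coherent_seq,coherent_pos,incoherent_seq,incoherent_pos
alarm ringing,4.74,Waking up,3,INC05,3
barking,1.23,House visitor,2,INC03,3
birds chirping,1.18,Waking up,5,INC02,4
fog horn,3.97,Ocean side,2,INC02,2
tires screeching,1.37,Car accident,2,INC01,2
busy signal,2.55,Phone call,5,INC05,5
crashing,4.85,Car accident,4,INC03,5
dialing,5.26,Phone call,4,INC04,1
dial tone,2.09,Phone call,3,INC02,3
doorbell,1.93,House visitor,1,INC04,4
door closing,2.06,House visitor,4,INC02,1
driving,2.17,Car accident,1,INC02,5
honking,0.92,Car accident,3,INC04,2
dog panting,2.18,House visitor,5,INC05,2
phone ringing,2.93,Phone call,1,INC03,2
pickup receiver,0.56,Phone call,2,INC01,4
rooster,1.64,Waking up,2,INC04,3
seagulls,1.98,Ocean side,1,INC05,4
police siren,3.88,Car accident,5,INC05,1
snoring,3.72,Waking up,1,INC03,4
splash,1.96,Ocean side,5,INC03,1
trotting,6.58,House visitor,3,INC01,5
footsteps,5.04,Ocean side,4,INC04,5
waves crashing,2.55,Ocean side,3,INC01,3
yawning,2.38,Waking up,4,INC01,1
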
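stimulus,valence,optimal_action,p_good_optimal,good_points,bad_points
I1,reward,A,0.8,25,0
I2,reward,B,0.8,25,0
I3,punishment,A,0.8,0,-25
I4,punishment,B,0.8,0,-25
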
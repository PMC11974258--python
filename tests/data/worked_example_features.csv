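feature,value
total_duration,10.0
duration_no_pauses,8.0
total_words,12
wps,1.2
wps_np,1.5
distortions,1
aos,8.333333333333334
pe,1
pew,0.08333333333333333
false_starts,1
false_start_rate,0.1
filled_pauses,2
filled_pause_rate,0.2
scs,1
scs_rate,0.1
is_count,0
is_rate,0.0
open_class,7
closed_class,5
verbs,3
verb_rate,0.3
nouns,3
noun_rate,0.3
r_oc,1.4
r_cc,0.7142857142857143
pr_v,0.5
mean_freq,83.33333333333333
log_freq,1.920818753952375
sem_e,1
sem_ew,0.08333333333333333
utterances,2
ul,6.0
sentences,2
sentence_rate,0.2
nws,10
sl,5.0
r_sentences,1.0
embeddings,1
ses,2
sis,0
pr_ses,1.0
sp_rate,0.8333333333333334
msyn_e,1
r_msyn_e,0.1
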
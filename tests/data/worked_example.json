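{
 "subject_id": "WE01",
 "session_id": "v0",
 "language": "it",
 "timing": {"total_duration_s": 10.0, "pause_duration_s": 2.0},
 "utterances": [
  {"id": 1, "tokens": [
   {"surface": "il", "kind": "word", "word_class": "closed", "pos": "function"},
   {"surface": "cane", "kind": "word", "word_class": "open", "pos": "noun", "lemma": "cane"},
   {"surface": "corre", "kind": "word", "word_class": "open", "pos": "verb"},
   {"surface": "eh", "kind": "filled_pause"},
   {"surface": "nel", "kind": "word", "word_class": "closed", "pos": "function"},
   {"surface": "parco", "kind": "word", "word_class": "open", "pos": "noun", "lemma": "parco", "flags": ["phonological_error"]}
  ]},
  {"id": 2, "tokens": [
   {"surface": "la", "kind": "word", "word_class": "closed", "pos": "function"},
   {"surface": "bam", "kind": "false_start"},
   {"surface": "bambina", "kind": "word", "word_class": "open", "pos": "noun", "lemma": "bambina"},
   {"surface": "e'", "kind": "word", "word_class": "closed", "pos": "auxiliary_be_have"},
   {"surface": "caduta", "kind": "word", "word_class": "open", "pos": "verb", "flags": ["phonotactic_distortion"]},
   {"surface": "e", "kind": "word", "word_class": "closed", "pos": "function"},
   {"surface": "piange", "kind": "word", "word_class": "open", "pos": "verb", "flags": ["semantic_error"]},
   {"surface": "mm", "kind": "filled_pause"},
   {"surface": "molto", "kind": "word", "word_class": "open", "pos": "adverb"}
  ]}
 ],
 "sentences": [
  {"utterance_id": 1, "start": 0, "end": 6, "subject_type": "expressed", "is_embedding": false, "is_incomplete": false, "msyn_errors": 0},
  {"utterance_id": 2, "start": 0, "end": 9, "subject_type": "expressed", "is_embedding": true, "is_incomplete": false, "msyn_errors": 1}
 ],
 "scs": [
  {"utterance_id": 1, "start": 4, "end": 6}
 ]
}
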
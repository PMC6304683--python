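{
 "name": "sc1",
 "populations": {
  "source": "ne_source",
  "early_colony": "ne_early_colony",
  "colony_a": "ne_colony_a",
  "colony_b": "ne_colony_b",
  "founder_lineage": "ne_founder"
 },
 "events": [
  {
   "kind": "split",
   "time": "t1",
   "derived": [
    "colony_a",
    "colony_b"
   ],
   "ancestral": "founder_lineage"
  },
  {
   "kind": "split",
   "time": "t2",
   "derived": [
    "early_colony"
   ],
   "ancestral": "founder_lineage"
  },
  {
   "kind": "split",
   "time": "t3",
   "derived": [
    "founder_lineage"
   ],
   "ancestral": "source"
  }
 ],
 "sampled": [
  "source",
  "early_colony",
  "colony_a",
  "colony_b"
 ],
 "generation_length_years": 5.0
}
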
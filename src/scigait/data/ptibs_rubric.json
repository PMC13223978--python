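{
  "scale": "PTIBS",
  "description": "Porcine Thoracic Injury Behaviour Scale: 10 ordinal locomotor stages from no active hindlimb movement (1) to normal ambulation (10). Levels 1-3 are 'dragging', 4-6 'stepping', 7-10 'walking'. Levels marked provisional carry paraphrased descriptors consistent with the scale's structure; substitute the original scale's wording when available.",
  "levels": [
    {"level": 1, "category": "dragging", "key": "no active hindlimb movements",
     "descriptor": "No active hindlimb movements.", "provisional": false},
    {"level": 2, "category": "dragging", "key": "active hindlimb movements, rump and knees on ground",
     "descriptor": "Active hindlimb movements with rump and knees constantly on the ground.", "provisional": false},
    {"level": 3, "category": "dragging", "key": "active hindlimb movements, rump or knees intermittently off ground",
     "descriptor": "Active hindlimb movements, rump or knees intermittently off the ground; hindlimbs still dragging.", "provisional": true},
    {"level": 4, "category": "stepping", "key": "occasional weight-bearing stepping",
     "descriptor": "Occasional weight-bearing extensions/steps; unable to take two consecutive steps with rump and knees off the ground.", "provisional": true},
    {"level": 5, "category": "stepping", "key": "frequent weight-bearing stepping",
     "descriptor": "Frequent weight-bearing steps; up to five consecutive steps with rump and knees off the ground.", "provisional": true},
    {"level": 6, "category": "stepping", "key": "consistent weight-bearing stepping",
     "descriptor": "Consistent weight-bearing stepping; more than five consecutive steps with rump and knees off the ground.", "provisional": true},
    {"level": 7, "category": "walking", "key": "walking with marked trunk instability",
     "descriptor": "Walking with knees fully extended but marked trunk instability.", "provisional": true},
    {"level": 8, "category": "walking", "key": "more than six steps, knees extended, plantar hoof placement, unbalanced trunk",
     "descriptor": "More than six steps with knees fully extended; plantar hoof placement with unbalanced trunk.", "provisional": false},
    {"level": 9, "category": "walking", "key": "normal ambulation, mild balance deficits",
     "descriptor": "Normal ambulation with mild balance deficits.", "provisional": true},
    {"level": 10, "category": "walking", "key": "normal ambulation, normal balance",
     "descriptor": "Normal ambulation with normal balance.", "provisional": false}
  ]
}
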
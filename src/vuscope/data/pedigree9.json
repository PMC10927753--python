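{
  "family_id": "9",
  "variant": "c.503C>T",
  "proband": "II-1",
  "individuals": [
    {"id": "I-1", "sex": "M", "father": null, "mother": null, "affected": false, "cancer_type": null, "age_dx": null, "tested": false, "carrier": null},
    {"id": "I-2", "sex": "F", "father": null, "mother": null, "affected": true, "cancer_type": "breast", "age_dx": 72, "tested": false, "carrier": null},
    {"id": "I-3", "sex": "F", "father": null, "mother": null, "affected": true, "cancer_type": "breast", "age_dx": 40, "tested": false, "carrier": null},
    {"id": "II-1", "sex": "M", "father": "I-1", "mother": "I-2", "affected": true, "cancer_type": "breast", "age_dx": 57, "tested": true, "carrier": true},
    {"id": "II-2", "sex": "F", "father": "I-1", "mother": "I-2", "affected": true, "cancer_type": "breast", "age_dx": 64, "tested": true, "carrier": false}
  ]
}
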
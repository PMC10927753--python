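{
  "family_id": "8",
  "variant": "c.1412C>T",
  "proband": "III-1",
  "individuals": [
    {"id": "I-1", "sex": "M", "father": null, "mother": null, "affected": false, "cancer_type": null, "age_dx": null, "tested": false, "carrier": null},
    {"id": "I-2", "sex": "F", "father": null, "mother": null, "affected": false, "cancer_type": null, "age_dx": null, "tested": false, "carrier": null},
    {"id": "II-1", "sex": "M", "father": "I-1", "mother": "I-2", "affected": false, "cancer_type": null, "age_dx": null, "tested": false, "carrier": null},
    {"id": "II-2", "sex": "F", "father": null, "mother": null, "affected": false, "cancer_type": null, "age_dx": null, "tested": false, "carrier": null},
    {"id": "III-1", "sex": "F", "father": "II-1", "mother": "II-2", "affected": true, "cancer_type": "breast", "age_dx": 39, "tested": true, "carrier": true},
    {"id": "III-2", "sex": "F", "father": "II-1", "mother": "II-2", "affected": true, "cancer_type": "breast", "age_dx": 39, "tested": true, "carrier": true}
  ]
}
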
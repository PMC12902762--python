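# Default tiered screening battery: RHS-13 gateway (Tier 1),
# four short forms (Tier 2), four full scales (Tier 3).
# Short-form item maps are configuration, not code; the PCL-5
# short form here samples one item per DSM-5 symptom cluster.
name: i-TAP default battery
scales:
- scale_id: rhs13
  disorder: distress
  cutoff: 11
  items: [rhs13_1, rhs13_2, rhs13_3, rhs13_4, rhs13_5, rhs13_6, rhs13_7, rhs13_8, rhs13_9, rhs13_10, rhs13_11,
    rhs13_12, rhs13_13]
- scale_id: phq9
  disorder: depression
  cutoff: 10
  items: [phq9_1, phq9_2, phq9_3, phq9_4, phq9_5, phq9_6, phq9_7, phq9_8, phq9_9]
- scale_id: gad7
  disorder: anxiety
  cutoff: 10
  items: [gad7_1, gad7_2, gad7_3, gad7_4, gad7_5, gad7_6, gad7_7]
- scale_id: pcl5
  disorder: ptsd
  cutoff: 32
  items: [pcl5_1, pcl5_2, pcl5_3, pcl5_4, pcl5_5, pcl5_6, pcl5_7, pcl5_8, pcl5_9, pcl5_10, pcl5_11, pcl5_12,
    pcl5_13, pcl5_14, pcl5_15, pcl5_16, pcl5_17, pcl5_18, pcl5_19, pcl5_20]
- scale_id: isi7
  disorder: insomnia
  cutoff: 11
  items: [isi7_1, isi7_2, isi7_3, isi7_4, isi7_5, isi7_6, isi7_7]
- scale_id: phq2
  disorder: depression
  cutoff: 2
  items: &id001 [phq9_1, phq9_2]
- scale_id: gad2
  disorder: anxiety
  cutoff: 2
  items: &id002 [gad7_1, gad7_2]
- scale_id: pcl5sf
  disorder: ptsd
  cutoff: 5
  items: &id003 [pcl5_1, pcl5_4, pcl5_7, pcl5_10]
- scale_id: isi_gate
  disorder: insomnia
  cutoff: 2
  items: &id004 [isi7_7]
items:
- {item_id: rhs13_1, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item1}
- {item_id: rhs13_2, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item2}
- {item_id: rhs13_3, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item3}
- {item_id: rhs13_4, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item4}
- {item_id: rhs13_5, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item5}
- {item_id: rhs13_6, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item6}
- {item_id: rhs13_7, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item7}
- {item_id: rhs13_8, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item8}
- {item_id: rhs13_9, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item9}
- {item_id: rhs13_10, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item10}
- {item_id: rhs13_11, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item11}
- {item_id: rhs13_12, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item12}
- {item_id: rhs13_13, scale_id: rhs13, min: 0, max: 4, text_key: rhs13.item13}
- {item_id: phq9_1, scale_id: phq9, min: 0, max: 3, text_key: phq9.item1}
- {item_id: phq9_2, scale_id: phq9, min: 0, max: 3, text_key: phq9.item2}
- {item_id: phq9_3, scale_id: phq9, min: 0, max: 3, text_key: phq9.item3}
- {item_id: phq9_4, scale_id: phq9, min: 0, max: 3, text_key: phq9.item4}
- {item_id: phq9_5, scale_id: phq9, min: 0, max: 3, text_key: phq9.item5}
- {item_id: phq9_6, scale_id: phq9, min: 0, max: 3, text_key: phq9.item6}
- {item_id: phq9_7, scale_id: phq9, min: 0, max: 3, text_key: phq9.item7}
- {item_id: phq9_8, scale_id: phq9, min: 0, max: 3, text_key: phq9.item8}
- {item_id: phq9_9, scale_id: phq9, min: 0, max: 3, text_key: phq9.item9}
- {item_id: gad7_1, scale_id: gad7, min: 0, max: 3, text_key: gad7.item1}
- {item_id: gad7_2, scale_id: gad7, min: 0, max: 3, text_key: gad7.item2}
- {item_id: gad7_3, scale_id: gad7, min: 0, max: 3, text_key: gad7.item3}
- {item_id: gad7_4, scale_id: gad7, min: 0, max: 3, text_key: gad7.item4}
- {item_id: gad7_5, scale_id: gad7, min: 0, max: 3, text_key: gad7.item5}
- {item_id: gad7_6, scale_id: gad7, min: 0, max: 3, text_key: gad7.item6}
- {item_id: gad7_7, scale_id: gad7, min: 0, max: 3, text_key: gad7.item7}
- {item_id: pcl5_1, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item1}
- {item_id: pcl5_2, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item2}
- {item_id: pcl5_3, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item3}
- {item_id: pcl5_4, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item4}
- {item_id: pcl5_5, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item5}
- {item_id: pcl5_6, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item6}
- {item_id: pcl5_7, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item7}
- {item_id: pcl5_8, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item8}
- {item_id: pcl5_9, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item9}
- {item_id: pcl5_10, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item10}
- {item_id: pcl5_11, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item11}
- {item_id: pcl5_12, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item12}
- {item_id: pcl5_13, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item13}
- {item_id: pcl5_14, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item14}
- {item_id: pcl5_15, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item15}
- {item_id: pcl5_16, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item16}
- {item_id: pcl5_17, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item17}
- {item_id: pcl5_18, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item18}
- {item_id: pcl5_19, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item19}
- {item_id: pcl5_20, scale_id: pcl5, min: 0, max: 4, text_key: pcl5.item20}
- {item_id: isi7_1, scale_id: isi7, min: 0, max: 4, text_key: isi7.item1}
- {item_id: isi7_2, scale_id: isi7, min: 0, max: 4, text_key: isi7.item2}
- {item_id: isi7_3, scale_id: isi7, min: 0, max: 4, text_key: isi7.item3}
- {item_id: isi7_4, scale_id: isi7, min: 0, max: 4, text_key: isi7.item4}
- {item_id: isi7_5, scale_id: isi7, min: 0, max: 4, text_key: isi7.item5}
- {item_id: isi7_6, scale_id: isi7, min: 0, max: 4, text_key: isi7.item6}
- {item_id: isi7_7, scale_id: isi7, min: 0, max: 4, text_key: isi7.item7}
tiers:
  1: [rhs13]
  2: [phq2, gad2, pcl5sf, isi_gate]
  3: [phq9, gad7, pcl5, isi7]
maps:
- short: phq2
  parent: phq9
  items: *id001
- short: gad2
  parent: gad7
  items: *id002
- short: pcl5sf
  parent: pcl5
  items: *id003
- short: isi_gate
  parent: isi7
  items: *id004
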
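- name: forest_agricultural_soil
  weights:
    modular cis-AT: 0.4772727272727272
    cis-loading module: 0.022727272727272724
    olefin synthase: 0.022727272727272724
    iterative aromatic: 0.022727272727272724
    iterative PTM: 0.0909090909090909
    trans-AT: 0.022727272727272724
    hybrid trans-AT: 0.022727272727272724
    hybrid cis-AT: 0.24999999999999997
    PUFA: 0.022727272727272724
    enediyne: 0.022727272727272724
    FAS: 0.022727272727272724
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: rhizosphere
  weights:
    modular cis-AT: 0.3809523809523809
    cis-loading module: 0.023809523809523805
    olefin synthase: 0.023809523809523805
    iterative aromatic: 0.023809523809523805
    iterative PTM: 0.023809523809523805
    trans-AT: 0.09523809523809522
    hybrid trans-AT: 0.023809523809523805
    hybrid cis-AT: 0.3333333333333333
    PUFA: 0.023809523809523805
    enediyne: 0.023809523809523805
    FAS: 0.023809523809523805
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: peat_soil
  weights:
    modular cis-AT: 0.39473684210526316
    cis-loading module: 0.02631578947368421
    olefin synthase: 0.02631578947368421
    iterative aromatic: 0.15789473684210525
    iterative PTM: 0.02631578947368421
    trans-AT: 0.02631578947368421
    hybrid trans-AT: 0.02631578947368421
    hybrid cis-AT: 0.23684210526315788
    PUFA: 0.02631578947368421
    enediyne: 0.02631578947368421
    FAS: 0.02631578947368421
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: freshwater
  weights:
    modular cis-AT: 0.2432432432432432
    cis-loading module: 0.027027027027027025
    olefin synthase: 0.13513513513513511
    iterative aromatic: 0.027027027027027025
    iterative PTM: 0.027027027027027025
    trans-AT: 0.027027027027027025
    hybrid trans-AT: 0.027027027027027025
    hybrid cis-AT: 0.2162162162162162
    PUFA: 0.2162162162162162
    enediyne: 0.027027027027027025
    FAS: 0.027027027027027025
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: freshwater_sediment
  weights:
    modular cis-AT: 0.2857142857142857
    cis-loading module: 0.02857142857142857
    olefin synthase: 0.02857142857142857
    iterative aromatic: 0.02857142857142857
    iterative PTM: 0.02857142857142857
    trans-AT: 0.1714285714285714
    hybrid trans-AT: 0.02857142857142857
    hybrid cis-AT: 0.02857142857142857
    PUFA: 0.3142857142857143
    enediyne: 0.02857142857142857
    FAS: 0.02857142857142857
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: seawater
  weights:
    modular cis-AT: 0.02564102564102564
    cis-loading module: 0.02564102564102564
    olefin synthase: 0.02564102564102564
    iterative aromatic: 0.02564102564102564
    iterative PTM: 0.02564102564102564
    trans-AT: 0.02564102564102564
    hybrid trans-AT: 0.02564102564102564
    hybrid cis-AT: 0.1794871794871795
    PUFA: 0.48717948717948717
    enediyne: 0.12820512820512822
    FAS: 0.02564102564102564
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: marine_sediment
  weights:
    modular cis-AT: 0.02564102564102564
    cis-loading module: 0.02564102564102564
    olefin synthase: 0.02564102564102564
    iterative aromatic: 0.02564102564102564
    iterative PTM: 0.02564102564102564
    trans-AT: 0.12820512820512822
    hybrid trans-AT: 0.02564102564102564
    hybrid cis-AT: 0.02564102564102564
    PUFA: 0.4358974358974359
    enediyne: 0.23076923076923075
    FAS: 0.02564102564102564
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
- name: host_associated
  weights:
    modular cis-AT: 0.2432432432432432
    cis-loading module: 0.027027027027027025
    olefin synthase: 0.027027027027027025
    iterative aromatic: 0.027027027027027025
    iterative PTM: 0.027027027027027025
    trans-AT: 0.3513513513513513
    hybrid trans-AT: 0.18918918918918917
    hybrid cis-AT: 0.027027027027027025
    PUFA: 0.027027027027027025
    enediyne: 0.027027027027027025
    FAS: 0.027027027027027025
  lineage_count: 4
  identity_target: 0.9
  full_length_fraction: 0.8
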
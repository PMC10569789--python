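{
  "_schema": {
    "description": "Genotype -> gating-cycle rate constants (1/s) at 25 C, saturating ATP, prephosphorylated channels. Provenance tags: 'measured' = published experimental estimate; 'derived' = computed from published fold-relations or equilibria; 'assumed' = package design choice.",
    "rates": ["k_open", "k_1", "k_minus1", "k_2", "k_OC", "k_CO"],
    "units": "1/s"
  },
  "WT": {
    "rates": {"k_open": 1.0, "k_1": 4.0, "k_minus1": 0.03, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: interburst lifetime ~1 s for phosphorylated channels in ATP",
      "k_1": "measured: hydrolysis rate ~4-5 /s at room temperature; 4 /s adopted",
      "k_minus1": "measured: true non-hydrolytic closing rate ~0.03 /s (K1250A/E1371S burst stability)",
      "k_2": "assumed: 50 /s; B2 lifetime short vs B1 (k_2 >> k_1), kept visible at 20 ms",
      "k_OC": "derived: gives intraburst P_o = 0.91 with k_CO = 100 /s",
      "k_CO": "derived: flickery closures last ~10 ms"
    }
  },
  "hE1371S": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.03, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: catalytic glutamate substitution abolishes hydrolysis",
      "k_minus1": "measured: ~0.03 /s, matches K1250A and WT true k_minus1",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hK1250A": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.03, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: Walker A lysine mutation abolishes hydrolysis",
      "k_minus1": "measured: ~0.03 /s, matches E1371S",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hE1371Q": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.0025, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: catalytic glutamate substitution abolishes hydrolysis",
      "k_minus1": "measured: ~0.0025 /s; burst stabilized by non-native Q1371-G576 H-bond",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hD1370N": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.5, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: Walker B aspartate mutation abolishes hydrolysis",
      "k_minus1": "measured: ~0.5-1 /s published range; lower bound adopted",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hK1250A_E1371Q": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.006, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: both mutations individually abolish hydrolysis",
      "k_minus1": "derived: E1371Q slows K1250A closure ~5-fold (0.03 / 5)",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hD1370N_E1371Q": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.03125, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: both mutations individually abolish hydrolysis",
      "k_minus1": "derived: E1371Q slows D1370N closure ~16-fold (0.5 / 16)",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hE1371Q_G576del": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.05, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: as hE1371Q",
      "k_minus1": "derived: G576 deletion accelerates hE1371Q closure ~20-fold (0.0025 x 20)",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: intraburst K_eq within ~2-fold of background; kept as WT",
      "k_CO": "derived: as WT"
    }
  },
  "hE1371S_G576del": {
    "rates": {"k_open": 1.0, "k_1": 0.0, "k_minus1": 0.06, "k_2": 50.0, "k_OC": 9.9, "k_CO": 100.0},
    "provenance": {
      "k_open": "assumed: as WT",
      "k_1": "measured: as hE1371S",
      "k_minus1": "derived: G576 deletion accelerates hE1371S closure ~2-fold (0.03 x 2)",
      "k_2": "assumed: as WT (unvisited when k_1 = 0)",
      "k_OC": "derived: intraburst K_eq within ~2-fold of background; kept as WT",
      "k_CO": "derived: as WT"
    }
  }
}
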
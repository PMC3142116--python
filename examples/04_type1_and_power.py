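"""Small type-I-error and power experiments with the replication harness.

Runs a reduced-scale version of the package's calibration experiments:
family-wise type-I under the homogeneous null, and paired power of the
three pipelines when a disease locus explains 5% of trait variance in a
structured population. Reduced sizes keep this under a minute; the
acceptance suite runs the full preregistered sizes.

Run:  python examples/04_type1_and_power.py
"""

from famjoint import (SimulationConfig, null_experiment, power_experiment,
                      summarize_tables)

null_cfg = SimulationConfig(population="homogeneous", n_families=200,
                            n_markers=500, map_length=2.8, seed=0)
t1 = null_experiment(null_cfg, ["joint", "b_screen"],
                     n_replicates=40, seed=0, K=10, l=300)

alt_cfg = SimulationConfig(population="structured", n_families=300,
                           n_markers=500, map_length=2.8, h=0.05,
                           disease_model="additive", mu=2.0, seed=0)
pw = power_experiment(alt_cfg, ["joint", "aftsa", "ftsa"],
                      n_replicates=40, seed=0, K=10, L_genomic=300)

table = summarize_tables(list(t1.values()) + list(pw.values()))
print(table.to_string(index=False,
                      formatters={"rate": "{:.3f}".format,
                                  "mc_stderr": "{:.3f}".format}))
print("\nExpected pattern: joint >= aftsa >> ftsa in power (the unadjusted "
      "screen is confounded by the mu = 2 stratification and rarely ranks "
      "the disease locus in the top R), and null rates near 0.05.")
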
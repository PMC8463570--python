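"""Run Hommola, ParaFit, and PACo under the true and a randomized host tree.

Two regimes: a single co-diversified lineage (the symbiont backbone
mirrors the host phylogeny) and a host-switch regime (host-restricted
radiations placed discordantly). The battery exposes the key caveat: with
many host-restricted radiations, all three tests stay 'significant' even
after the host phylogeny is randomized, so they cannot distinguish
co-diversification from host-restricted diversification.
"""

import cophylorestrict as cp

for scenario, n_clades, asvs in (("codiversification", 1, 4),
                                 ("host_switch", 10, 8)):
    cfg = cp.ScenarioConfig(scenario=scenario, n_clades_per_host=n_clades,
                            asvs_per_clade=asvs,
                            captive_human_acquisition=0.0, rng_seed=3)
    data = cp.simulate_scenario(cfg)
    assoc = cp.association_from_incidence(data.incidence, data.samples)
    config = cp.AnalysisConfig(n_permutations=999, rng_seed=3)
    table = cp.host_randomization_battery(
        data.host_tree, data.symbiont_tree, assoc, config, config.rng())
    print(f"\n=== {scenario} ({data.incidence.shape[0]} ASVs) ===")
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))

# In the codiversification regime the true host tree is decisively
# significant (p at the 0.001 floor) while the randomized host is weaker
# or non-significant. In the host-switch regime p <= 0.05 everywhere —
# including the randomized host — reproducing the false-positive
# phenomenon: the tests detect host restriction, not congruence.
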
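"""Shared helpers for the test suite."""

from conftest import simulate, trivariate_truth


def small_sim_dataset(seed=11):
    ds, _ = simulate(trivariate_truth(), 50, 50, seed=seed,
                     singleton_fraction=0.2,
                     missing_fraction={"prs": 0.1})
    return ds
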
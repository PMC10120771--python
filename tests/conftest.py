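import pytest

import spliceotype as st


@pytest.fixture(scope="session")
def toy_ann():
    return st.toy_annotation()


def quantify(sim, annotation, config=None):
    """Run the quantification chain on a simulation: records -> PSI matrix."""
    records = [r for recs in sim.records_by_sample.values() for r in recs]
    groups = st.build_anchor_groups(records, annotation)
    counts = st.counts_frame(records)
    return st.compute_psi(groups, counts, config or st.QuantConfig())


def differential(sim, annotation, reference="WT", config=None):
    psi = quantify(sim, annotation, config)
    return st.delta_psi(psi, sim.genotype_map, reference, config or st.QuantConfig())


@pytest.fixture(scope="session")
def default_sim(toy_ann):
    """One default simulation shared by read-only tests."""
    return st.simulate_junction_counts(toy_ann, st.default_splice_config(seed=11))
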
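import numpy as np
import pandas as pd
import pytest

from tldkit import simulate, tnseq


@pytest.fixture
def small_insertions() -> pd.DataFrame:
    """Hand-built insertion table spanning two genes and an intergenic site."""
    rows = []
    for sample in ("start", "t0", "t3"):
        rows += [
            {"chrom": "chr", "pos": 150, "strand": "+", "sample": sample, "count": 7},
            {"chrom": "chr", "pos": 180, "strand": "-", "sample": sample, "count": 3},
            {"chrom": "chr", "pos": 201, "strand": "+", "sample": sample, "count": 5},
            {"chrom": "chr", "pos": 420, "strand": "+", "sample": sample, "count": 11},
        ]
    return pd.DataFrame(rows)


@pytest.fixture
def small_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB"],
            "chrom": ["chr", "chr"],
            "start": [100, 400],
            "end": [200, 500],
            "strand": ["+", "-"],
        }
    )


@pytest.fixture(scope="session")
def tnseq_sim():
    """A moderate simulated library with known effects, analysed once."""
    rng = np.random.default_rng(42)
    effect_genes = rng.choice(600, size=60, replace=False)
    effects = {int(g): float(s) for g, s in zip(effect_genes, rng.uniform(-3, 4, 60))}
    truth = simulate.TnseqTruth(n_genes=600, depth=3e6, effects=effects)
    insertions, annotation = simulate.sim_tnseq(truth, seed=7)
    gene_counts, site_table = tnseq.aggregate_footprints(insertions, annotation)
    gst = tnseq.survival_scores(gene_counts)
    return {
        "truth": truth,
        "effects": effects,
        "insertions": insertions,
        "annotation": annotation,
        "gene_counts": gene_counts,
        "site_table": site_table,
        "gst": gst,
    }


@pytest.fixture(scope="session")
def flow_sim():
    """One simulated acquisition with a -0.5 log2 strain shift, fully processed."""
    import warnings

    from tldkit import flow

    truth = simulate.FlowTruth(
        strains={"thyA_plus": 0.0, "thyA_minus_starved": -0.5},
        n_batches=3,
        n_reps=4,
        events_per_cell=400,
    )
    events = simulate.sim_flow(truth, seed=11)
    gated = flow.gate_events(events)
    model = flow.fit_autofluorescence(gated[gated["is_nodye"]], seed=0)
    adjusted = flow.subtract_autofluorescence(gated, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = flow.fit_size_model(adjusted, reference="thyA_plus")
    return {
        "truth": truth,
        "events": events,
        "gated": gated,
        "model": model,
        "adjusted": adjusted,
        "fit": fit,
    }
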
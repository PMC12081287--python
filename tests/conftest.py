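import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucite import (
    NucleusDataset,
    SimulationConfig,
    default_effect_table,
    simulate_dataset,
)


def build_dataset(
    counts,
    antibodies=("H3", "TDP43"),
    A=None,
    hashtag=None,
    donor_id=None,
    disease_group="young",
    batch="batch0",
    cell_type="capillary",
    cluster=None,
    genes=None,
):
    """Construct a small NucleusDataset from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    barcodes = [f"bc{i:03d}" for i in range(n)]
    if genes is None:
        genes = [f"g{j:03d}" for j in range(g)]
    if A is None:
        A = np.full((n, len(antibodies)), 100, dtype=np.int64)
    meta = pd.DataFrame(
        {
            "donor_id": donor_id if donor_id is not None else ["d0"] * n,
            "disease_group": disease_group,
            "batch": batch,
            "hashtag_counts": hashtag if hashtag is not None else [100] * n,
            "total_counts": counts.sum(axis=1).astype(int),
            "cell_type": cell_type,
        },
        index=barcodes,
    )
    if cluster is not None:
        meta["cluster"] = cluster
    return NucleusDataset(
        barcodes=barcodes,
        genes=list(genes),
        antibodies=list(antibodies),
        X=sp.csr_matrix(counts),
        A=np.asarray(A, dtype=np.int64),
        meta=meta,
    )


@pytest.fixture(scope="session")
def cohort():
    """A default-scale simulated cohort with planted effects."""
    config = SimulationConfig(seed=11, effect_table=default_effect_table())
    ds, truth = simulate_dataset(config)
    return ds, truth


@pytest.fixture(scope="session")
def qc_cohort(cohort):
    """The cohort after QC, with normalized expression and nCLR levels."""
    from nucite import (
        add_model_covariates,
        normalize_expression,
        qc_filter,
        quantify_proteins,
    )

    ds, truth = cohort
    ds_qc, report = qc_filter(ds)
    norm = normalize_expression(ds_qc.X)
    meta = add_model_covariates(ds_qc.meta, ds_qc.total_counts)
    levels = quantify_proteins(ds_qc.antibody_frame())
    return {
        "ds": ds_qc,
        "truth": truth,
        "report": report,
        "norm": norm,
        "meta": meta,
        "levels": levels,
    }
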
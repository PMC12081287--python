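"""Reference normalization and nCLR transform of antibody capture counts.

Antibody capture counts confound nuclear protein abundance with a
per-nucleus capture-efficiency scalar (antibody access, permeability,
tag recovery). Dividing every antibody of a nucleus by its histone H3
counts cancels that scalar, because H3 abundance is nearly constant per
nucleus:

    n_p[i, p] = (A[i, p] + pc) / (A[i, ref] + pc)

The reference-normalized values are then put on an additive scale by a
centered natural log-ratio ("nCLR"): the log of each value minus the
log geometric mean of that antibody over a centering cohort of nuclei,
so the per-antibody cohort mean of nCLR is zero. An alternative
per-nucleus centering axis (across antibodies) is provided behind a
flag; under that axis the reference cancels algebraically, which is why
per-antibody centering is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DEFAULT_REFERENCE_ANTIBODY, logger

#: labels used with the default cuts (0.25, 0.75, 0.90)
DEFAULT_CUT_LABELS = ("bottom25", "mid", "top10_25", "top10")
QUINTILE_CUTS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class ProteinLevels:
    """Reference-normalized (``n_p``) and nCLR-transformed protein values."""

    n_p: pd.DataFrame  # nuclei x antibodies, dimensionless ratios
    nclr: pd.DataFrame  # nuclei x antibodies, log scale, cohort-centered
    reference: str
    pseudocount: float
    zero_reference: pd.Index  # nuclei whose raw reference count was 0


def normalize_to_reference(
    A: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE_ANTIBODY,
    pseudocount: float = 1.0,
):
    """Divide each antibody column by the reference antibody column.

    Returns ``(n_p, zero_reference)`` where ``zero_reference`` indexes
    nuclei whose raw reference count is zero: with ``pseudocount=0``
    their ratios are undefined and they must be excluded from protein
    analyses.
    """
    if reference not in A.columns:
        raise ValueError(f"reference antibody {reference!r} absent from panel")
    A = A.astype(float)
    zero_ref = A.index[A[reference] == 0]
    if len(zero_ref):
        logger.warning(
            "%d nuclei have zero reference (%s) counts", len(zero_ref), reference
        )
    denom = A[reference] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        n_p = (A + pseudocount).div(denom, axis=0)
    return n_p, zero_ref


def clr_transform(
    n_p: pd.DataFrame,
    cohort_mask=None,
    axis: str = "antibody",
) -> pd.DataFrame:
    """Centered natural log-ratio of reference-normalized values.

    ``axis="antibody"`` (default) centers each antibody by its geometric
    mean across the cohort nuclei: nclr[i,p] = ln(n_p[i,p]) - mean over
    cohort of ln(n_p[.,p]), so the per-antibody log-mean over the cohort
    is zero. ``axis="nucleus"`` centers each nucleus across antibodies
    instead (classical compositional CLR).

    ``cohort_mask`` selects the nuclei that define the centering; all
    nuclei are transformed.
    """
    if axis not in {"antibody", "nucleus"}:
        raise ValueError(f"axis must be 'antibody' or 'nucleus', got {axis!r}")
    vals = n_p.to_numpy(dtype=float)
    if cohort_mask is None:
        cohort = np.ones(len(n_p), dtype=bool)
    else:
        cohort = np.asarray(cohort_mask, dtype=bool)
        if cohort.shape != (len(n_p),) or not cohort.any():
            raise ValueError("cohort_mask must be a non-empty nucleus mask")
    sub = vals[cohort]
    if (~np.isfinite(sub)).any() or (sub <= 0).any():
        raise ValueError(
            "non-positive normalized values in the centering cohort; "
            "use a pseudocount in normalize_to_reference"
        )
    with np.errstate(divide="ignore"):
        logv = np.log(vals)
    if axis == "antibody":
        center = logv[cohort].mean(axis=0)[None, :]
    else:
        center = logv.mean(axis=1)[:, None]
    return pd.DataFrame(logv - center, index=n_p.index, columns=n_p.columns)


def quantify_proteins(
    A: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE_ANTIBODY,
    pseudocount: float = 1.0,
    cohort_mask=None,
    axis: str = "antibody",
) -> ProteinLevels:
    """Reference normalization followed by the nCLR transform."""
    n_p, zero_ref = normalize_to_reference(A, reference, pseudocount)
    nclr = clr_transform(n_p, cohort_mask=cohort_mask, axis=axis)
    return ProteinLevels(
        n_p=n_p,
        nclr=nclr,
        reference=reference,
        pseudocount=pseudocount,
        zero_reference=zero_ref,
    )


def assign_percentile_bins(
    values: pd.Series,
    cuts=(0.25, 0.75, 0.90),
    within=None,
    labels=None,
) -> pd.Series:
    """Label nuclei by the percentile band their protein value falls in.

    Thresholds are the empirical quantiles of ``values`` over the
    ``within`` subset only (default: all nuclei); nuclei outside the
    subset get a missing label. Ties: a value equal to a threshold goes
    to the lower bin. With the default cuts the labels are
    ``bottom25/mid/top10_25/top10``; quintile cuts (0.2, 0.4, 0.6, 0.8)
    yield ``q1..q5``; otherwise generic ``bin0..binK``.
    """
    cuts = tuple(cuts)
    if any(not 0 < c < 1 for c in cuts) or list(cuts) != sorted(set(cuts)):
        raise ValueError("cuts must be strictly increasing fractions in (0, 1)")
    if within is None:
        sub = np.ones(len(values), dtype=bool)
    else:
        sub = np.asarray(within, dtype=bool)
        if not sub.any():
            raise ValueError("percentile subset is empty")
    min_spacing = min(
        b - a for a, b in zip((0.0,) + cuts, cuts + (1.0,))
    )
    if sub.sum() < 1.0 / min_spacing:
        warnings.warn(
            f"subset of {int(sub.sum())} nuclei is small for cuts {cuts}; "
            "bins assigned anyway"
        )
    if labels is None:
        if cuts == (0.25, 0.75, 0.90):
            labels = list(DEFAULT_CUT_LABELS)
        elif cuts == QUINTILE_CUTS:
            labels = [f"q{i}" for i in range(1, 6)]
        else:
            labels = [f"bin{i}" for i in range(len(cuts) + 1)]
    if len(labels) != len(cuts) + 1:
        raise ValueError("need one label per bin (len(cuts) + 1)")

    v = values.to_numpy(dtype=float)
    thresholds = np.quantile(v[sub], cuts)
    # value <= threshold -> lower bin (documented tie rule)
    bin_idx = np.searchsorted(thresholds, v, side="left")
    out = pd.Series(pd.array([None] * len(v), dtype="object"), index=values.index)
    out[sub] = [labels[i] for i in bin_idx[sub]]
    return out


def embedding_density(embedding, subset_mask) -> np.ndarray:
    """Gaussian-kernel density of a nucleus subset over a 2-D embedding.

    Fits a Gaussian KDE to the embedding coordinates of the subset
    (e.g. nuclei in the top decile of a protein) and evaluates it at
    every nucleus's position, min-max scaled to [0, 1].
    """
    from scipy.stats import gaussian_kde

    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2 or emb.shape[1] != 2:
        raise ValueError("embedding must be an (n, 2) array")
    mask = np.asarray(subset_mask, dtype=bool)
    if mask.sum() < 10:
        raise ValueError(
            f"subset has {int(mask.sum())} nuclei; at least 10 required"
        )
    pts = emb[mask].T
    if np.allclose(pts.var(axis=1), 0):
        raise ValueError("degenerate embedding: subset points are identical")
    dens = gaussian_kde(pts)(emb.T)
    lo, hi = dens.min(), dens.max()
    if hi == lo:
        raise ValueError("degenerate embedding: constant density")
    return (dens - lo) / (hi - lo)
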
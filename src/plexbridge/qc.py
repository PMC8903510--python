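"""Quality control, structure, and annotation analyses of the abundance matrix.

Covers replicate Spearman correlation (pairwise-complete, average ranks for
ties), PCA on the complete-entry submatrix (centered per protein, no unit
scaling — abundances already share a log2 scale post-normalization), Ward/
Euclidean hierarchical clustering, per-sample Z scoring, dropout accounting
per the complete / inter-plex / intra-plex missingness taxonomy, vitreous
hemoglobin subphenotyping, and plasma/erythroid blood-protein annotation.

Dropout classes: a protein measured in every sample of every plex is
*complete*; one measured in every sample of each plex where it appears at
all, but wholly absent from at least one plex, shows *inter-plex* dropout
(data-dependent acquisition undersampling); one missing for a strict subset
of samples within some plex shows *intra-plex* dropout. Intra-plex takes
precedence when both patterns occur, so the three classes partition the
proteins observed anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .types import ClinicalAnnotation, PlexDesign, QuantMatrix

__all__ = [
    "DropoutSummary",
    "SubphenotypeLabel",
    "spearman_matrix",
    "pca_scores",
    "ward_cluster",
    "zscore_by_sample",
    "dropout_accounting",
    "classify_subphenotype",
    "annotate_blood",
    "DEFAULT_PLASMA_GENES",
    "DEFAULT_RBC_GENES",
    "HB_BANDS",
]

# Default blood-protein annotation lists. These are synthetic reconstructions:
# the 23 most abundant plasma proteins by mass (the classic set dominated by
# albumin, immunoglobulins, transferrin, haptoglobin, ...) and 7 genes
# expressed >=1000-fold higher in erythroid than non-erythroid cells. Both
# are overridable by the caller; overlap resolves erythroid-first.
DEFAULT_PLASMA_GENES: tuple[str, ...] = (
    "ALB", "IGHG1", "IGHA1", "IGHM", "TF", "HP", "A2M", "SERPINA1",
    "C3", "APOA1", "APOA2", "APOB", "TTR", "HPX", "ORM1", "FGA",
    "FGB", "FGG", "CP", "PLG", "C4A", "AGT", "AHSG",
)
DEFAULT_RBC_GENES: tuple[str, ...] = (
    "HBA1", "HBB", "HBD", "CA1", "AHSP", "SLC4A1", "BPGM",
)

# Vitreous hemoglobin subphenotype bands (g/dL), endpoints inclusive;
# concentrations falling in the gaps between bands are left unclassified.
HB_BANDS: dict[str, tuple[float, float]] = {
    "PDR-L": (0.0, 1.00e-4),
    "PDR-M": (2.00e-4, 1.70e-3),
    "PDR-H": (4.90e-3, 8.40e-3),
}


@dataclass
class DropoutSummary:
    """Partition of proteins by missingness pattern across plexes."""

    n_total: int
    n_complete: int
    n_interplex: int
    n_intraplex: int
    per_sample_measured: pd.Series = field(default_factory=pd.Series)
    classes: pd.Series = field(default_factory=pd.Series)  # per-entry class label

    def __post_init__(self) -> None:
        assert self.n_complete + self.n_interplex + self.n_intraplex == self.n_total


@dataclass(frozen=True)
class SubphenotypeLabel:
    sample_id: str
    label: str  # CTL | PDR-L | PDR-M | PDR-H | unclassified
    hemoglobin: float


def spearman_matrix(
    a: QuantMatrix, samples: Sequence[str] | None = None, min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation between sample columns.

    Each pair is computed on the entries nonmissing in both samples, with
    average ranks for ties. Pairs sharing fewer than ``min_shared`` entries
    get a missing cell (with a warning). Invariant under any strictly
    increasing per-sample transform of the abundances.
    """
    cols = list(samples) if samples is not None else a.sample_ids
    if len(cols) < 2:
        raise ValueError("need at least two samples")
    sub = a.values[cols]
    corr = sub.corr(method="spearman", min_periods=min_shared)
    notna = sub.notna()
    shared = notna.T.astype(int) @ notna.astype(int)
    thin = (shared < min_shared).to_numpy()
    np.fill_diagonal(thin, False)
    if thin.any():
        warnings.warn(
            f"{int(thin.sum()) // 2} sample pair(s) share fewer than "
            f"{min_shared} entries; cells left missing",
            RuntimeWarning,
        )
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca_scores(
    a: QuantMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the complete-entry submatrix.

    Entries with any missing cell are excluded; each protein is centered
    across samples (no unit-variance scaling). Returns per-sample scores and
    the explained-variance fractions (summing to <= 1). Requests for more
    components than the data supports are reduced with a warning.
    """
    complete = a.values.dropna(axis=0, how="any")
    n_entries, n_samples = complete.shape
    if n_entries < 2 or n_samples < 3:
        raise ValueError("need >= 2 complete entries and >= 3 samples for PCA")
    max_comp = min(n_entries, n_samples - 1)
    if n_components > max_comp:
        warnings.warn(
            f"reducing components from {n_components} to {max_comp}", RuntimeWarning
        )
        n_components = max_comp
    x = complete.to_numpy(dtype=float).T  # samples x entries
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    var = s**2 / (n_samples - 1)
    frac = var[:n_components] / var.sum()
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=complete.columns, columns=cols), frac


def ward_cluster(
    a: QuantMatrix,
    axis: str = "samples",
    n_clusters: int = 2,
    exclude: Sequence[str] | None = None,
    restrict: Sequence[str] | None = None,
):
    """Agglomerative Ward clustering on Euclidean distances of complete entries.

    ``axis`` selects whether samples or entries are clustered. ``exclude`` /
    ``restrict`` filter the entry set (e.g. dropping, or keeping only, the
    blood-protein panel) before clustering. Deterministic for a fixed input:
    scipy's linkage with observation-order tie-breaking; leaves ordered by
    the linkage's standard left-to-right traversal.

    Returns (linkage matrix, cluster labels as a Series, leaf order list).
    """
    complete = a.values.dropna(axis=0, how="any")
    if exclude is not None:
        complete = complete.loc[[e for e in complete.index if e not in set(exclude)]]
    if restrict is not None:
        complete = complete.loc[[e for e in complete.index if e in set(restrict)]]
    if complete.empty:
        raise ValueError("complete-entry submatrix is empty")
    if axis == "samples":
        x = complete.to_numpy(dtype=float).T
        names = list(complete.columns)
    elif axis == "entries":
        x = complete.to_numpy(dtype=float)
        names = list(complete.index)
    else:
        raise ValueError("axis must be 'samples' or 'entries'")
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    leaves = [names[i] for i in hierarchy.leaves_list(z)]
    return z, pd.Series(labels, index=names, name="cluster"), leaves


def dendrogram_newick(z: np.ndarray, names: Sequence[str]) -> str:
    """Serialize a scipy linkage as a Newick-style nested string."""
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree) + ";"


def zscore_by_sample(a: QuantMatrix) -> QuantMatrix:
    """Per-sample Z scores: subtract the sample mean, divide by its SD (ddof=1).

    Missing cells stay missing and are excluded from the moments. A sample
    with zero SD or fewer than two nonmissing values is an error.
    """
    v = a.values
    counts = v.notna().sum(axis=0)
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"samples with < 2 nonmissing values: {bad}")
    sd = v.std(axis=0, ddof=1, skipna=True)
    if (sd == 0).any():
        raise ValueError(f"zero SD in samples: {list(sd.index[sd == 0])}")
    z = v.sub(v.mean(axis=0, skipna=True), axis=1).div(sd, axis=1)
    return QuantMatrix(z, level=a.level, kind="zscore")


def _plex_of_sample(designs: Sequence[PlexDesign]) -> dict[str, str]:
    return {
        d.global_sample_id(c): d.plex_id for d in designs for c in d.sample_channels()
    }


def classify_presence(present_by_plex: Mapping[str, tuple[int, int]]) -> str:
    """Classify one protein's (n_measured, n_samples) per plex.

    Returns 'complete', 'interplex', 'intraplex', or 'absent'. Intra-plex
    (a strict subset measured within some plex) takes precedence over
    inter-plex (whole plexes absent).
    """
    fracs = list(present_by_plex.values())
    if all(m == 0 for m, _ in fracs):
        return "absent"
    if any(0 < m < n for m, n in fracs):
        return "intraplex"
    if any(m == 0 for m, _ in fracs):
        return "interplex"
    return "complete"


def dropout_accounting(
    a: QuantMatrix, designs: Sequence[PlexDesign]
) -> tuple[DropoutSummary, pd.DataFrame]:
    """Classify every entry's missingness pattern and emit set memberships.

    Returns the class partition plus an upset-style membership table: per
    entry, a boolean column per sample and a per-plex presence pattern
    string ('full', 'partial', 'none').
    """
    plex_of = _plex_of_sample(designs)
    cols = [s for s in a.sample_ids if s in plex_of]
    present = a.values[cols].notna()
    plex_ids = [d.plex_id for d in designs]
    by_plex_cols = {k: [s for s in cols if plex_of[s] == k] for k in plex_ids}

    classes = {}
    patterns = {}
    for entry, row in present.iterrows():
        per_plex = {
            k: (int(row[cs].sum()), len(cs)) for k, cs in by_plex_cols.items()
        }
        classes[entry] = classify_presence(per_plex)
        patterns[entry] = "|".join(
            ("full" if m == n else "none" if m == 0 else "partial")
            for m, n in per_plex.values()
        )
    cls = pd.Series(classes, name="dropout_class")
    observed = cls[cls != "absent"]
    summary = DropoutSummary(
        n_total=int(len(observed)),
        n_complete=int((observed == "complete").sum()),
        n_interplex=int((observed == "interplex").sum()),
        n_intraplex=int((observed == "intraplex").sum()),
        per_sample_measured=present.sum(axis=0),
        classes=cls,
    )
    membership = present.copy()
    membership["plex_pattern"] = pd.Series(patterns)
    membership["dropout_class"] = cls
    return summary, membership


def classify_subphenotype(c: ClinicalAnnotation) -> SubphenotypeLabel:
    """Map a PDR sample to its hemoglobin subphenotype band (CTL stays CTL).

    Band endpoints are inclusive; hemoglobin values in the gaps between the
    bands are 'unclassified' (with a warning) rather than snapped to the
    nearest band.
    """
    if c.phenotype != "PDR":
        return SubphenotypeLabel(c.sample_id, "CTL", c.hemoglobin)
    hb = c.hemoglobin
    if np.isnan(hb) or hb < 0:
        raise ValueError(f"sample {c.sample_id}: PDR sample needs hemoglobin >= 0")
    for label, (lo, hi) in HB_BANDS.items():
        if lo <= hb <= hi:
            return SubphenotypeLabel(c.sample_id, label, hb)
    warnings.warn(
        f"sample {c.sample_id}: hemoglobin {hb:g} g/dL falls between subphenotype "
        "bands; left unclassified",
        RuntimeWarning,
    )
    return SubphenotypeLabel(c.sample_id, "unclassified", hb)


def annotate_blood(
    entries: Sequence[str],
    plasma_set: Sequence[str] | None = None,
    rbc_set: Sequence[str] | None = None,
) -> dict[str, str]:
    """Label each entry plasma / rbc / other; erythroid wins on overlap."""
    plasma = set(DEFAULT_PLASMA_GENES if plasma_set is None else plasma_set)
    rbc = set(DEFAULT_RBC_GENES if rbc_set is None else rbc_set)
    out = {}
    for e in entries:
        if e in rbc:
            out[e] = "rbc"
        elif e in plasma:
            out[e] = "plasma"
        else:
            out[e] = "other"
    return out
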
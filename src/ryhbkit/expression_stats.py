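"""qRT-PCR reference-gene normalization and fold-change inference.

The data model is the standard nested qRT-PCR design: several technical
replicate wells inside each biological replicate, for each gene and
strain.  Expression is normalized per sample by subtracting the mean
reference-gene Ct of the same (strain, biological replicate) — the
delta-Ct convention, so expression is proportional to 2^-deltaCt.
Technical replicates are averaged inside each biological replicate and
the contrast between two strains is tested across biological replicates
with a two-sided t-test (pooled variance by default, matching the
balanced mixed-model reduction and exactly calibrated at small n;
``welch=True`` gives the unequal-variance test).  For a balanced design
the averaging reduction is exactly the mixed-model contrast for nested
biological/technical variance components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["gene", "strain", "bio_rep", "tech_rep", "ct"]


class CtTable:
    """Replicate-structured Ct measurements (gene, strain, bio_rep, tech_rep, ct).

    Non-finite Ct values (undetermined wells) are dropped with a warning,
    never imputed.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        df = df[REQUIRED_COLUMNS].copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        bad = ~np.isfinite(df["ct"])
        if bad.any():
            logger.warning("dropping %d undetermined Ct wells", int(bad.sum()))
            df = df[~bad]
        if df.empty:
            raise ValueError("Ct table has no usable rows")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    @property
    def strains(self) -> list[str]:
        return sorted(self.df["strain"].unique())


class NormalizedExpr:
    """delta-Ct per (gene, strain, bio_rep); the reference gene is identically 0."""

    def __init__(self, delta_ct: pd.Series, reference_gene: str):
        self.delta_ct = delta_ct  # MultiIndex (gene, strain, bio_rep)
        self.reference_gene = reference_gene

    def values_for(self, gene: str, strain: str) -> np.ndarray:
        try:
            sub = self.delta_ct.loc[gene, strain]
        except KeyError:
            raise KeyError(f"no measurements for gene {gene!r} in strain {strain!r}") from None
        return np.asarray(sub.sort_index(), dtype=float)


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    contrast: tuple[str, str]  # (strain_A, strain_B); FC is B relative to A
    fold_change: float
    p_value: float  # NaN for the reference gene (zero variance by construction)
    n_a: int
    n_b: int

    @property
    def significant(self) -> Optional[bool]:
        if math.isnan(self.p_value):
            return None
        return self.p_value < 0.05


def normalize(table: CtTable, reference_gene: str = "recA") -> NormalizedExpr:
    """Per-sample delta-Ct: gene mean Ct minus reference mean Ct, per
    (strain, biological replicate), technical replicates averaged."""
    means = table.df.groupby(["gene", "strain", "bio_rep"])["ct"].mean()
    if reference_gene not in means.index.get_level_values("gene"):
        raise ValueError(f"reference gene {reference_gene!r} not in the table")
    ref = means.loc[reference_gene]
    idx = means.index
    sample_idx = pd.MultiIndex.from_arrays(
        [idx.get_level_values("strain"), idx.get_level_values("bio_rep")]
    )
    ref_vals = ref.reindex(sample_idx).to_numpy()
    if np.isnan(ref_vals).any():
        i = int(np.flatnonzero(np.isnan(ref_vals))[0])
        strain, rep = sample_idx[i]
        raise ValueError(
            f"reference gene {reference_gene!r} missing in sample "
            f"(strain={strain!r}, bio_rep={rep})"
        )
    delta = pd.Series(means.to_numpy() - ref_vals, index=idx, name="delta_ct")
    return NormalizedExpr(delta, reference_gene)


def relative_level(expr: NormalizedExpr, gene: str, strain: str) -> float:
    """Expression level relative to the reference gene: 2^(-mean delta-Ct)."""
    vals = expr.values_for(gene, strain)
    return float(2.0 ** (-np.mean(vals)))


def fold_change(
    expr: NormalizedExpr,
    gene: str,
    strain_a: str,
    strain_b: str,
    welch: bool = False,
) -> FoldChangeResult:
    """Fold change of `gene` in strain_b relative to strain_a, with a
    two-sided t-test across biological replicates.

    FC = 2^(mean deltaCt_A - mean deltaCt_B), so up-regulation in B
    gives FC > 1.  The pooled-variance test is the default (it is the
    balanced-design mixed-model contrast and holds its nominal size at
    n=3); ``welch=True`` switches to the unequal-variance test, which is
    conservative at small replicate counts.  The reference gene has zero
    variance by construction and is reported with FC 1 and p = NaN.
    """
    a = expr.values_for(gene, strain_a)
    b = expr.values_for(gene, strain_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"{gene}: need >= 2 biological replicates per strain "
            f"(got {len(a)} vs {len(b)})"
        )
    fc = float(2.0 ** (np.mean(a) - np.mean(b)))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate (e.g. the reference gene itself): no variance to test
        p = float("nan")
    else:
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return FoldChangeResult(gene, (strain_a, strain_b), fc, p, len(a), len(b))


def fold_change_table(
    table: CtTable,
    strain_a: str,
    strain_b: str,
    reference_gene: str = "recA",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene fold changes for one contrast, in a report-ready frame."""
    expr = normalize(table, reference_gene)
    rows = []
    for gene in table.genes:
        try:
            r = fold_change(expr, gene, strain_a, strain_b, welch)
        except KeyError:
            continue
        rows.append(
            {
                "gene": gene,
                "contrast": f"{strain_b} vs {strain_a}",
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
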
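"""Relative-expression analysis by the comparative Ct (2^-ddCt) method.

A Ct table (gene x organ x condition x timepoint x replicate) is reduced
to fold changes of each gene relative to a reference gene (default
ACTIN), treated versus mock: ddCt = (Ct_gene - Ct_ref)_treated -
(Ct_gene - Ct_ref)_mock and fold = 2^-ddCt, so log2 fold = -ddCt.
dCt is computed per replicate and then averaged (not Ct averaged first),
and the per-replicate dCt values feed a two-sample Student's t-test.
Amplification efficiency is assumed to be exactly 2 throughout.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REFERENCE_GENE = "ACTIN"

CT_COLUMNS = ["gene", "organ", "condition", "timepoint", "replicate", "ct"]


class CtTableError(ValueError):
    """Malformed Ct table or missing reference measurements."""


def validate_ct_table(ct: pd.DataFrame, reference: str = REFERENCE_GENE
                      ) -> pd.DataFrame:
    """Check the tidy Ct layout and that Ct values are finite."""
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise CtTableError(f"Ct table missing columns {sorted(missing)}")
    if not np.isfinite(ct["ct"]).all():
        raise CtTableError("non-finite Ct values")
    if reference not in set(ct["gene"]):
        raise CtTableError(f"reference gene {reference!r} absent")
    return ct


def read_ct_table(path, reference: str = REFERENCE_GENE) -> pd.DataFrame:
    """Read a Ct TSV (columns gene/organ/condition/timepoint/replicate/ct)."""
    return validate_ct_table(pd.read_csv(path, sep="\t"), reference)


# ---------------------------------------------------------------------------
# Core arithmetic
# ---------------------------------------------------------------------------

def delta_delta_ct(
    ct_gene_trt: float,
    ct_ref_trt: float,
    ct_gene_mock: float,
    ct_ref_mock: float,
) -> float:
    """Fold change 2^-ddCt from four (replicate-mean) Ct values."""
    for v in (ct_gene_trt, ct_ref_trt, ct_gene_mock, ct_ref_mock):
        if v is None or not np.isfinite(v):
            raise CtTableError("missing Ct value in ddCt computation")
    ddct = (ct_gene_trt - ct_ref_trt) - (ct_gene_mock - ct_ref_mock)
    return float(2.0 ** (-ddct))


def _dct_replicates(
    ct: pd.DataFrame, gene: str, organ: str, condition: str,
    timepoint, reference: str,
) -> np.ndarray:
    """Per-replicate dCt = Ct_gene - Ct_ref, matched on replicate index."""
    cell = ct[(ct["organ"] == organ) & (ct["condition"] == condition)
              & (ct["timepoint"] == timepoint)]
    g = cell[cell["gene"] == gene].set_index("replicate")["ct"]
    r = cell[cell["gene"] == reference].set_index("replicate")["ct"]
    if r.empty:
        raise CtTableError(
            f"reference {reference!r} missing in "
            f"({organ}, {condition}, {timepoint})"
        )
    common = g.index.intersection(r.index)
    return (g.loc[common] - r.loc[common]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Tissue profile
# ---------------------------------------------------------------------------

def tissue_profile(
    ct: pd.DataFrame,
    organs: list[str],
    reference: str = REFERENCE_GENE,
    anchor_organ: str = "cotyledon",
) -> pd.DataFrame:
    """Relative abundance per gene and organ, anchored to the reference.

    abundance(g, o) = 2^(Ct_ref(o) - Ct_g(o)) from replicate-mean Cts,
    then the matrix is rescaled so that the reference gene's abundance in
    the anchor organ equals 1 after division by 1000 (i.e. the reference
    anchor cell reads 1000 units).  Missing gene/organ cells are NaN, not
    zero.
    """
    validate_ct_table(ct, reference)
    means = (
        ct.groupby(["gene", "organ"])["ct"].mean().unstack("organ")
    )
    if reference not in means.index:
        raise CtTableError(f"reference {reference!r} absent")
    for o in organs:
        if o not in means.columns or pd.isna(means.loc[reference, o]):
            raise CtTableError(f"reference not measured in organ {o!r}")
    genes = [g for g in means.index if g != reference]
    out = pd.DataFrame(index=genes + [reference], columns=organs, dtype=float)
    for g in out.index:
        for o in organs:
            if o in means.columns and not pd.isna(means.loc[g, o]):
                out.loc[g, o] = 2.0 ** (
                    means.loc[reference, o] - means.loc[g, o]
                )
    if anchor_organ not in organs:
        raise CtTableError(f"anchor organ {anchor_organ!r} not profiled")
    # reference's anchor abundance is 1 pre-scaling; x1000 makes the
    # "reference anchor / 1000 = 1" convention hold
    anchor = out.loc[reference, anchor_organ]
    return out * (1000.0 / anchor)


# ---------------------------------------------------------------------------
# Time-course contrasts
# ---------------------------------------------------------------------------

FCM_COLUMNS = [
    "gene", "organ", "timepoint", "fold", "log2fc", "pvalue", "direction",
]


def timecourse_contrast(
    ct: pd.DataFrame,
    condition_trt: str,
    condition_mock: str,
    timepoints: list | None = None,
    organs: list[str] | None = None,
    genes: list[str] | None = None,
    reference: str = REFERENCE_GENE,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Fold-change matrix of treated vs mock per gene/organ/timepoint.

    Folds come from replicate-mean dCt values; the p-value is a
    two-sample Student's t-test on the per-replicate dCt values
    (equal-variance by default, Welch via ``equal_var=False``).
    Direction is up/down by the sign of log2 fold when p < alpha, else
    ns.  Fewer than two replicates in either group leaves the p-value
    undefined (NaN), direction ns, with a warning.  No multiple-testing
    correction is applied; per-gene tests are reported as such.
    """
    validate_ct_table(ct, reference)
    if organs is None:
        organs = sorted(ct["organ"].unique())
    if timepoints is None:
        timepoints = sorted(ct["timepoint"].unique())
    if genes is None:
        genes = sorted(g for g in ct["gene"].unique() if g != reference)
    rows = []
    for g in genes:
        for o in organs:
            for t in timepoints:
                trt = _dct_replicates(ct, g, o, condition_trt, t, reference)
                mock = _dct_replicates(ct, g, o, condition_mock, t, reference)
                if len(trt) == 0 or len(mock) == 0:
                    raise CtTableError(
                        f"no measurements for {g} in ({o}, {t})"
                    )
                ddct = trt.mean() - mock.mean()
                fold = 2.0 ** (-ddct)
                if len(trt) < 2 or len(mock) < 2:
                    warnings.warn(
                        f"<2 replicates for {g} ({o}, {t}); p undefined",
                        stacklevel=2,
                    )
                    p = np.nan
                else:
                    with np.errstate(divide="ignore", invalid="ignore"), \
                            warnings.catch_warnings():
                        # near-zero variance trips a precision warning in
                        # the t machinery; the nan fallback below covers it
                        warnings.simplefilter("ignore", RuntimeWarning)
                        p = float(
                            stats.ttest_ind(
                                trt, mock, equal_var=equal_var
                            ).pvalue
                        )
                    if not np.isfinite(p):
                        # zero within-group variance: equal means carry no
                        # evidence, unequal noise-free means are certain
                        p = 1.0 if np.isclose(trt.mean(), mock.mean()) \
                            else 0.0
                if np.isfinite(p) and p < alpha:
                    direction = "up" if ddct < 0 else "down"
                else:
                    direction = "ns"
                rows.append((g, o, t, fold, -ddct, p, direction))
    return pd.DataFrame(rows, columns=FCM_COLUMNS)


def alleviation_score(
    fcm_infected: pd.DataFrame,
    fcm_infected_inhibitor: pd.DataFrame,
) -> pd.DataFrame:
    """How much an inhibitor damps the infection response.

    score(g, organ, t) = |log2FC infection alone| - |log2FC infection
    with inhibitor| (both contrasts against the common mock); positive
    means alleviation.
    """
    a = fcm_infected.set_index(["gene", "organ", "timepoint"])["log2fc"]
    b = fcm_infected_inhibitor.set_index(
        ["gene", "organ", "timepoint"]
    )["log2fc"]
    score = (a.abs() - b.abs()).rename("alleviation")
    return score.reset_index()


# ---------------------------------------------------------------------------
# Heat-map matrix
# ---------------------------------------------------------------------------

def heatmap_matrix(
    fcm: pd.DataFrame,
    figure_path=None,
) -> pd.DataFrame:
    """Genes x (organ, timepoint) matrix of log2 fold values.

    Optionally renders a heat map with a color scale symmetric about 0
    (rendering is off unless a path is given, keeping headless runs
    headless).
    """
    mat = fcm.pivot_table(
        index="gene", columns=["organ", "timepoint"], values="log2fc"
    )
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        lim = float(np.nanmax(np.abs(mat.to_numpy()))) or 1.0
        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * mat.shape[1]), max(3, 0.3 * mat.shape[0]))
        )
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim,
                       aspect="auto")
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_xticks(
            range(mat.shape[1]),
            [f"{o} {t}" for o, t in mat.columns],
            rotation=90,
        )
        fig.colorbar(im, ax=ax, label="log2 fold change")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return mat
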
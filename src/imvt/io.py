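"""Reading, writing and synthesizing expression studies.

Canonical interchange is tab-delimited text, the common export format for
normalized microarray matrices: probes as rows, a header of sample IDs, the
probe ID in column 1.  The phenotype table has one row per sample with a
binary condition column and optional covariates.

The fixture generator builds studies that emulate the statistical anatomy
of a real two-condition microarray experiment: a dominant inert background
factor carried by a small block of loud probes (the "PC1" of intensity
scaling, dominating study-wide variance without drowning the median
probe), a condition-mean-shifted minor factor and a condition-variance-
inflated minor factor (latent confounders), covariate effects (age,
menopausal status), and a set of planted MVDE probes whose per-condition
noise is shifted by r and scaled by (1 + s).  A truth table accompanies
the matrix for parameter-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import ExpressionStudy

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "load_study",
    "FixtureSpec",
    "generate_fixture",
    "write_fixture",
]


def read_expression(path, orientation: str = "probes_by_samples", delimiter: str = "\t") -> pd.DataFrame:
    """Read an expression matrix; returns a probes x samples DataFrame.

    ``orientation="samples_by_probes"`` transposes after reading.  Duplicate
    IDs and non-numeric cells are rejected with coordinates in the message.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated row IDs {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated column IDs {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    if orientation == "samples_by_probes":
        numeric = numeric.T
    elif orientation != "probes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return numeric


def write_expression(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a probes x samples DataFrame at full float precision."""
    df.to_csv(path, sep=delimiter, index_label="probe_id", float_format="%.17g")


def read_phenotype(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read the phenotype table (sample_id, condition, covariates...)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if "condition" not in df.columns:
        raise ValueError(f"{path}: phenotype table must have a 'condition' column")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample IDs {dup}")
    return df


def _coerce_covariate(col: pd.Series) -> pd.Series:
    """Numeric passthrough; binary text levels map 0/1 by sorted level name."""
    num = pd.to_numeric(col, errors="coerce")
    if not num.isna().any():
        return num.astype(float)
    levels = sorted(col.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"covariate {col.name!r} is non-numeric with {len(levels)} levels; "
            "only binary text covariates are supported"
        )
    return col.astype(str).map({levels[0]: 0.0, levels[1]: 1.0})


def load_study(
    expr_path,
    pheno_path,
    condition_col: str = "condition",
    covariate_cols: list[str] | None = None,
    orientation: str = "probes_by_samples",
    delimiter: str = "\t",
) -> ExpressionStudy:
    """Join an expression matrix with its phenotype table into a study.

    The join is by sample ID and order-insensitive; unmatched IDs on either
    side are an error.  A text condition column is mapped to 0/1 by sorted
    level name.
    """
    expr = read_expression(expr_path, orientation=orientation, delimiter=delimiter)
    pheno = read_phenotype(pheno_path, delimiter=delimiter)
    missing = [s for s in expr.columns if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing}")
    pheno = pheno.loc[list(expr.columns)]
    cond_raw = pheno[condition_col]
    levels = sorted(cond_raw.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"condition column {condition_col!r} must have exactly 2 levels, got {levels}"
        )
    condition = cond_raw.astype(str).map({levels[0]: 0, levels[1]: 1}).to_numpy()
    if covariate_cols is None:
        covariate_cols = [c for c in pheno.columns if c != condition_col]
    covariates = None
    if covariate_cols:
        covariates = pd.DataFrame(
            {c: _coerce_covariate(pheno[c]) for c in covariate_cols},
            index=pheno.index,
        ).reset_index(drop=True)
    return ExpressionStudy(
        matrix=expr.to_numpy(dtype=float),
        probe_ids=[str(p) for p in expr.index],
        sample_ids=[str(s) for s in expr.columns],
        condition=condition,
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

#: Planted effect sizes cycled over the planted probes: (r, s) = mean shift
#: in noise-SD units and spread increment of the condition-2 noise.
DEFAULT_PLANTED_EFFECTS = ((1.3, 0.0), (0.0, 1.8), (0.9, 0.9))


@dataclass(frozen=True)
class FixtureSpec:
    """Design of a synthetic two-condition expression study.

    The dominant background factor loads on a small block of loud probes
    (``dominant_probe_fraction``), so it dominates the study-wide PCA like
    an array-intensity PC1 while leaving the median probe testable and its
    chance condition alignment unable to move genome-wide medians.  The two
    condition-associated minor factors are the latent confounders the
    calibration pipeline must find and remove: one mean-shifted between
    conditions (also heteroscedastic, so its PC is detectable through the
    variance channel whose removal barely costs the mean tests), one purely
    variance-inflated in condition 2.  Factor scores keep their natural
    sampling variation: zeroing the chance per-condition means would break
    the null consistency of the t statistics (factor variance in the
    denominator with no matching numerator term) and deflate every loaded
    probe.  Planted probes carry their condition effect in the
    idiosyncratic noise and do not load on the dominant factor.
    """

    n_probes: int = 5000
    n1: int = 40
    n2: int = 40
    n_planted: int = 50
    planted_effects: tuple[tuple[float, float], ...] = DEFAULT_PLANTED_EFFECTS
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    dominant_probe_fraction: float = 0.02
    dominant_loading_sigma: float = 1.0
    dominant_mean_square_loading: float = 60.0
    mean_factor_loading_sd: float = 0.18
    mean_factor_shift: float = 0.45
    mean_factor_inflation: float = 3.0
    var_factor_loading_sd: float = 0.26
    var_factor_inflation: float = 4.0
    covariate_loading_sd: float = 0.28
    age_condition_shift: float = 1.2
    family: str = "NORMAL"
    seed: int = 0

    def __post_init__(self):
        if self.n_planted > self.n_probes:
            raise ValueError("more planted probes than probes")
        for r, s in self.planted_effects:
            if s <= -1:
                raise ValueError("planted s must exceed -1")
        if self.family.upper() not in ("NORMAL", "LAPLACE"):
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "planted_effects" in d:
            d["planted_effects"] = tuple(tuple(e) for e in d["planted_effects"])
        return cls(**d)


def generate_fixture(spec: FixtureSpec) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Generate a synthetic study and its planted-truth table.

    Deterministic given ``spec.seed``.  The truth table has one row per
    planted probe: probe_id, r, s.
    """
    rng = np.random.default_rng(spec.seed)
    m, n1, n2 = spec.n_probes, spec.n1, spec.n2
    n = n1 + n2
    cond = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    probe_ids = [f"probe_{i:05d}" for i in range(m)]
    sample_ids = [f"s{j:03d}" for j in range(n)]

    planted = np.sort(rng.choice(m, size=spec.n_planted, replace=False))
    effects = [spec.planted_effects[k % len(spec.planted_effects)] for k in range(spec.n_planted)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=m)

    # dominant inert factor: carried by a small block of loud probes (the
    # array-intensity-like PC1), with heavy-tailed loadings inside the
    # block normalized to a fixed total strength so the factor's share of
    # study-wide variance is stable across seeds.  Confining the factor to
    # a block keeps its chance condition alignment from moving the
    # genome-wide median test statistic.
    n_loud = max(1, int(round(spec.dominant_probe_fraction * m)))
    quiet = np.setdiff1d(np.arange(m), planted)
    loud = rng.choice(quiet, size=min(n_loud, quiet.size), replace=False)
    a1 = np.zeros(m)
    a1[loud] = rng.lognormal(0.0, spec.dominant_loading_sigma, size=loud.size)
    a1 *= np.sqrt(spec.dominant_mean_square_loading * m / np.sum(a1**2))
    f1 = rng.standard_normal(n)

    # latent confounders.  The mean-shifted factor is also heteroscedastic
    # between conditions: its scores are detectable through the variance
    # channel, whose removal costs the downstream mean tests almost
    # nothing, so the mean shift itself can stay small.
    a2 = rng.normal(0.0, spec.mean_factor_loading_sd, size=m)
    f2 = rng.standard_normal(n)
    f2[cond == 1] *= 1.0 + spec.mean_factor_inflation
    f2 = f2 + spec.mean_factor_shift * cond
    a3 = rng.normal(0.0, spec.var_factor_loading_sd, size=m)
    f3 = rng.standard_normal(n)
    f3[cond == 1] *= 1.0 + spec.var_factor_inflation

    # covariates: age (shifted between conditions) and menopausal status
    age = 50.0 + rng.normal(0.0, 8.0, size=n) + spec.age_condition_shift * cond
    # menopausal status tracks age but is balanced across conditions, so it
    # confounds probe variation without proxying the condition
    meno_score = age + rng.normal(0.0, 4.0, size=n)
    menopause = np.zeros(n)
    for g in (0, 1):
        idx = np.where(cond == g)[0]
        menopause[idx[np.argsort(meno_score[idx])[idx.size // 2 :]]] = 1.0
    age_z = (age - age.mean()) / age.std()
    b_age = rng.normal(0.0, spec.covariate_loading_sd, size=m)
    b_meno = rng.normal(0.0, spec.covariate_loading_sd, size=m)

    if spec.family.upper() == "NORMAL":
        eps = rng.standard_normal((m, n))
    else:
        eps = rng.laplace(0.0, 1.0, (m, n))
    for idx, (r, s) in zip(planted, effects):
        eps[idx, cond == 1] = r + (1.0 + s) * eps[idx, cond == 1]

    matrix = (
        baseline[:, None]
        + np.outer(a1, f1)
        + np.outer(a2, f2)
        + np.outer(a3, f3)
        + np.outer(b_age, age_z)
        + np.outer(b_meno, menopause - menopause.mean())
        + eps
    )

    covariates = pd.DataFrame({"age": age, "menopause": menopause})
    study = ExpressionStudy(
        matrix=matrix,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        condition=cond,
        covariates=covariates,
    )
    truth = pd.DataFrame(
        {
            "probe_id": [probe_ids[i] for i in planted],
            "r": [e[0] for e in effects],
            "s": [e[1] for e in effects],
        }
    )
    return study, truth


def write_fixture(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Generate a fixture and write expression/phenotype/truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study, truth = generate_fixture(spec)
    expr = pd.DataFrame(study.matrix, index=study.probe_ids, columns=study.sample_ids)
    paths = {
        "expression": outdir / "expression.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(expr, paths["expression"])
    pheno = pd.DataFrame(
        {
            "sample_id": study.sample_ids,
            "condition": [f"c{c}" for c in study.condition],
            "age": study.covariates["age"].to_numpy(),
            "menopause": study.covariates["menopause"].to_numpy(),
        }
    )
    pheno.to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.17g")
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    return paths
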
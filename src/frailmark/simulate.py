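"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group case/control study of physical frailty &
sarcopenia (PF&S): group sizes 22/27, covariate marginals matching the study
population table, right-skewed (log-normal) serum-marker marginals with
group-specific block correlation, and signed standardized group shifts on the
log scale for the markers reported as differing between groups.

Nothing here attempts to match the study's actual concentration
distributions (not published); defaults encode sample sizes, covariate
summaries, effect directions, and the cluster memberships visible in the
published per-group correlation heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import MARKER_NAMES, CohortTable

# Per-group covariate (mean, sd): PFS first, control second.
DEFAULT_COVARIATES = {
    "age": ((75.5, 4.7), (75.0, 4.4)),
    "bmi": ((29.9, 4.4), (26.6, 2.2)),
    "sppb": ((7.8, 1.6), (11.3, 0.9)),
    "alm": ((16.3, 3.6), (20.3, 4.0)),
    "alm_bmi": ((0.55, 0.12), (0.86, 0.28)),
    "n_diseases": ((2.5, 1.6), (1.8, 1.5)),
    "n_medications": ((3.3, 2.0), (2.9, 1.9)),
}

#: Female fraction per group (18/22 PF&S, 17/27 controls).
DEFAULT_SEX_PROB_FEMALE = (18 / 22, 17 / 27)

# Typical serum concentration scales (pg/mL or ng/mL depending on assay);
# log-normal location is ln(typical median), scale 0.5 throughout.
DEFAULT_LOG_MU = {
    "IL1β": np.log(0.5),
    "IL6": np.log(2.0),
    "TNFα": np.log(15.0),
    "ActivinA": np.log(400.0),
    "SerpinE1": np.log(20000.0),
    "ICAM1": np.log(200.0),
    "TIMP1": np.log(100.0),
    "GDF15": np.log(1200.0),
    "FGF21": np.log(200.0),
    "GFAP": np.log(100.0),
}
DEFAULT_LOG_SIGMA = {m: 0.5 for m in MARKER_NAMES}

# Signed standardized group shifts on the log scale (+ = higher in PF&S).
# Directions follow the reported group differences; magnitudes are set so the
# per-marker two-group tests at n=22/27 land in the reported significance
# bands (d~0.65 for p<0.05, ~0.85 for p<0.01, ~1.1 for p<0.001).
DEFAULT_EFFECT = {
    "IL1β": -0.85,
    "IL6": -0.85,
    "TNFα": 0.65,
    "ActivinA": 0.0,
    "SerpinE1": 0.0,
    "ICAM1": 0.65,
    "TIMP1": 1.1,
    "GDF15": 0.0,
    "FGF21": 0.0,
    "GFAP": -0.4,
}


def block_correlation(n: int, blocks: list[list[int]], rho: float) -> np.ndarray:
    """Identity-plus-blocks correlation: r=rho within each block, 0 across."""
    corr = np.eye(n)
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    corr[i, j] = rho
    return corr


def _default_corr_pfs() -> np.ndarray:
    # PF&S heatmap: {FGF21, ActivinA} vs the remaining eight markers.
    names = list(MARKER_NAMES)
    b1 = [names.index("FGF21"), names.index("ActivinA")]
    b2 = [i for i in range(10) if i not in b1]
    return block_correlation(10, [b1, b2], 0.45)


def _default_corr_control() -> np.ndarray:
    # Control heatmap: inflammatory trio vs remodeling/mitochondrial cluster.
    names = list(MARKER_NAMES)
    b1 = [names.index(m) for m in ("TNFα", "IL1β", "IL6")]
    b2 = [i for i in range(10) if i not in b1]
    return block_correlation(10, [b1, b2], 0.45)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator (defaults = study design)."""

    n_pfs: int = 22
    n_control: int = 27
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    sex_prob_female: tuple[float, float] = DEFAULT_SEX_PROB_FEMALE
    marker_names: tuple[str, ...] = MARKER_NAMES
    marker_log_mu: dict = field(default_factory=lambda: dict(DEFAULT_LOG_MU))
    marker_log_sigma: dict = field(default_factory=lambda: dict(DEFAULT_LOG_SIGMA))
    effect: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    corr_pfs: np.ndarray = field(default_factory=_default_corr_pfs)
    corr_control: np.ndarray = field(default_factory=_default_corr_control)
    #: Correlation between SPPB and the (negated) mean log-marker deviation;
    #: 0 keeps covariates independent of markers.
    sppb_marker_link: float = 0.0
    seed: int = 0


def _check_corr(corr: np.ndarray, p: int, label: str) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (p, p):
        raise ValueError(f"{label} correlation must be {p}x{p}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError(f"{label} correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError(f"{label} correlation must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError(f"{label} correlation is not positive semidefinite")
    return corr


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    # Cholesky with an eigen fallback for PSD-but-singular matrices.
    try:
        return np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _draw_group(
    rng: np.random.Generator,
    n: int,
    group: str,
    cfg: SyntheticConfig,
    corr: np.ndarray,
    shifted: bool,
    id_offset: int,
) -> dict:
    p = len(cfg.marker_names)
    L = _corr_factor(corr)
    z = rng.standard_normal((n, p)) @ L.T
    mu = np.array([cfg.marker_log_mu[m] for m in cfg.marker_names])
    sig = np.array([cfg.marker_log_sigma[m] for m in cfg.marker_names])
    eff = np.array([cfg.effect.get(m, 0.0) for m in cfg.marker_names])
    log_x = mu + sig * (z + (eff if shifted else 0.0))
    markers = np.exp(log_x)

    gi = 0 if group == "PFS" else 1
    cov = {}
    for name, params in cfg.covariate_params.items():
        m, s = params[gi]
        cov[name] = rng.normal(m, s, size=n)
    if cfg.sppb_marker_link != 0.0:
        # Tie SPPB to the latent marker profile: higher marker burden, lower SPPB.
        rho = float(np.clip(cfg.sppb_marker_link, -0.99, 0.99))
        latent = z.mean(axis=1)
        latent = (latent - latent.mean()) / (latent.std() + 1e-12)
        m, s = cfg.covariate_params["sppb"][gi]
        eps = rng.standard_normal(n)
        cov["sppb"] = m + s * (-rho * latent + np.sqrt(1 - rho**2) * eps)

    sex = np.where(rng.random(n) < cfg.sex_prob_female[gi], "F", "M")
    return {
        "subject_id": np.array([f"S{gi}{i + id_offset:04d}" for i in range(n)]),
        "group": np.full(n, group),
        "age": np.clip(cov["age"], 60.0, None),
        "sex": sex,
        "bmi": np.clip(cov["bmi"], 12.0, None),
        "sppb": np.clip(np.rint(cov["sppb"]), 0, 12).astype(int),
        "alm": np.clip(cov["alm"], 5.0, None),
        "alm_bmi": np.clip(cov["alm_bmi"], 0.05, None),
        "n_diseases": np.clip(np.rint(cov["n_diseases"]), 0, None).astype(int),
        "n_medications": np.clip(np.rint(cov["n_medications"]), 0, None).astype(int),
        "markers": markers,
    }


def generate_cohort(config: SyntheticConfig | None = None, seed: int | None = None) -> CohortTable:
    """Draw one synthetic cohort; reproducible given the seed.

    Markers are group-wise multivariate normal on the log scale (Cholesky of
    the group's correlation matrix), the PF&S group shifted by the signed
    per-marker effect in log-SD units, then exponentiated.
    """
    cfg = config if config is not None else SyntheticConfig()
    if seed is not None:
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": seed})
    if cfg.n_pfs < 2 or cfg.n_control < 2:
        raise ValueError("each group needs at least 2 subjects")
    p = len(cfg.marker_names)
    corr_p = _check_corr(cfg.corr_pfs, p, "PFS")
    corr_c = _check_corr(cfg.corr_control, p, "CONTROL")

    rng = np.random.default_rng(cfg.seed)
    g1 = _draw_group(rng, cfg.n_pfs, "PFS", cfg, corr_p, shifted=True, id_offset=0)
    g2 = _draw_group(rng, cfg.n_control, "CONTROL", cfg, corr_c, shifted=False, id_offset=0)

    merged = {k: np.concatenate([g1[k], g2[k]]) for k in g1}
    table = CohortTable(marker_names=tuple(cfg.marker_names), **merged)
    table.validate()
    return table


def _generic_names(n_markers: int) -> tuple[str, ...]:
    if n_markers == len(MARKER_NAMES):
        return MARKER_NAMES
    return tuple(f"M{i + 1}" for i in range(n_markers))


def make_null_cohort(n1: int, n2: int, n_markers: int, seed: int) -> CohortTable:
    """Negative control: every marker i.i.d. log-normal, independent of group."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    names = _generic_names(n_markers)
    cfg = SyntheticConfig(
        n_pfs=n1,
        n_control=n2,
        marker_names=names,
        marker_log_mu={m: 1.0 for m in names},
        marker_log_sigma={m: 0.5 for m in names},
        effect={m: 0.0 for m in names},
        corr_pfs=np.eye(n_markers),
        corr_control=np.eye(n_markers),
        seed=seed,
    )
    return generate_cohort(cfg)


def make_separable_cohort(
    n1: int,
    n2: int,
    informative: set[int] | list[int],
    shift: float,
    seed: int,
    n_markers: int = 10,
) -> CohortTable:
    """Positive control: the given marker columns shifted by ``shift`` log-SD
    in the PF&S group; all other markers null."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    informative = set(int(i) for i in informative)
    if shift > 0 and not informative:
        raise ValueError("informative set empty with nonzero shift")
    names = _generic_names(n_markers)
    cfg = SyntheticConfig(
        n_pfs=n1,
        n_control=n2,
        marker_names=names,
        marker_log_mu={m: 1.0 for m in names},
        marker_log_sigma={m: 0.5 for m in names},
        effect={m: (shift if i in informative else 0.0) for i, m in enumerate(names)},
        corr_pfs=np.eye(n_markers),
        corr_control=np.eye(n_markers),
        seed=seed,
    )
    return generate_cohort(cfg)
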
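"""Synthetic paired train/test immunotherapy cohorts with ground truth.

The generator emulates the structure the pipeline assumes in real trial
data: two bulk RNA-seq cohorts of negative-binomial counts, a minority
responder class (default prevalence 0.23, the responder fraction of a
~300-patient atezolizumab trial), a small set of response-informative
genes, per-gene domain shift between cohorts, and survival endpoints
driven by a subset of genes.

Domain-shift semantics: a "shifted" gene is *non-transferable* — in the
test cohort its marginal log-mean is displaced (by ``shift_location``
standard deviations of the gene's log2 expression) and its response
association, if any, is absent.  The displacement is the detectable marker
the KS filter keys on; the broken association is what makes such genes
worthless (or harmful) to a classifier carried across cohorts.  A uniform
displacement alone would be erased by per-cohort standardization and could
not degrade a classifier, so it would not exercise the method.

Counts are NB with Var = mu + phi mu^2; per-sample sequencing-depth factors
are lognormal so size-factor estimation has something to do.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, Unit, ValidationError

LN2 = float(np.log(2.0))

# expected gap E[z | z >= med] - E[z | z < med] for a standard normal;
# dividing the log-hazard exponent by it makes ``survival_hr`` the hazard
# ratio realized across a median split of a single survival gene
MEDIAN_SPLIT_GAP = 2.0 * float(np.sqrt(2.0 / np.pi))


@dataclass
class SimulationConfig:
    """Study conditions for a paired-cohort simulation.

    Defaults mirror the cohort structure of the trials the pipeline targets:
    ~23% responders, training cohort larger than the test cohort, a minority
    of informative genes with log2 effect sizes in [0.5, 1.5], and a subset
    of genes whose distribution shifts between cohorts.
    """

    n_genes: int = 2000
    n_train: int = 150
    n_test: int = 80
    prevalence: float = 0.23
    n_informative: int = 40
    lfc_low: float = 0.5
    lfc_high: float = 1.5
    nb_dispersion: float = 0.2  # mean of the gamma-distributed per-gene phi
    baseline_log2_mean: tuple[float, float] = (3.0, 10.0)
    n_shifted: int = 40
    shift_location: float = 2.0  # in SDs of the gene's log2 expression
    shift_scale: float = 1.0  # dispersion multiplier in the test cohort
    frac_informative_shifted: float = 0.0  # fraction of shifted genes that are informative
    n_survival_genes: int = 5
    survival_hr: float = 2.0
    median_os_months: float = 12.0
    censor_rate: float = 0.3
    depth_sd: float = 0.2  # lognormal sigma of per-sample depth factors
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")
        if self.n_informative > self.n_genes or self.n_shifted > self.n_genes:
            raise ValidationError("informative/shifted gene counts exceed n_genes")
        if not 0 <= self.frac_informative_shifted <= 1:
            raise ValidationError("frac_informative_shifted must be in [0, 1]")
        n_overlap = round(self.frac_informative_shifted * self.n_shifted)
        if n_overlap > self.n_informative:
            raise ValidationError("more informative-shifted genes than informative genes")
        if self.n_informative + self.n_shifted - n_overlap > self.n_genes:
            raise ValidationError("informative + shifted genes exceed n_genes")
        if self.n_survival_genes > self.n_genes:
            raise ValidationError("n_survival_genes exceeds n_genes")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated pair of cohorts."""

    informative_genes: dict[str, float]  # gene -> log2 fold change (responders vs non)
    shifted_genes: dict[str, dict]  # gene -> {location_sd, scale}
    survival_genes: dict[str, float]  # gene -> hazard ratio per SD of expression
    response_probability: float  # per-sample responder probability (Bernoulli)

    def as_dict(self) -> dict:
        return {
            "informative_genes": self.informative_genes,
            "shifted_genes": self.shifted_genes,
            "survival_genes": self.survival_genes,
            "response_probability": self.response_probability,
        }


@dataclass
class SimulatedData:
    train_counts: ExpressionMatrix
    train_clinical: ClinicalTable
    test_counts: ExpressionMatrix
    test_clinical: ClinicalTable
    gene_lengths: pd.Series
    truth: SimulationTruth


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with Var = mu + phi mu^2 (phi broadcast over columns)."""
    r = 1.0 / np.maximum(phi, 1e-12)
    if r.ndim == 1:
        r = r[:, None]
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, mean.shape), p).astype(float)


def _sd_log2(mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Delta-method SD of log2(count) around an NB(mu, phi) draw."""
    return np.sqrt(1.0 / mu + phi) / LN2


def simulate_cohorts(config: SimulationConfig) -> SimulatedData:
    """Generate a paired train/test dataset with full ground truth.

    Reproducible bit-for-bit from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    lengths = pd.Series(
        rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, cfg.n_genes),
        index=genes, name="length_bp",
    ).astype(float)

    log2_mu = rng.uniform(*cfg.baseline_log2_mean, cfg.n_genes)
    phi = rng.gamma(shape=2.0, scale=cfg.nb_dispersion / 2.0, size=cfg.n_genes)
    phi = np.maximum(phi, 1e-4)

    # assign roles: shifted genes overlap the informative set by the configured fraction
    n_overlap = round(cfg.frac_informative_shifted * cfg.n_shifted)
    perm = rng.permutation(cfg.n_genes)
    informative_idx = perm[: cfg.n_informative]
    shifted_idx = np.concatenate(
        [informative_idx[:n_overlap], perm[cfg.n_informative : cfg.n_informative + cfg.n_shifted - n_overlap]]
    ).astype(int)
    non_special = perm[cfg.n_informative + cfg.n_shifted - n_overlap :]
    if cfg.n_survival_genes > non_special.size:
        raise ValidationError("not enough genes left for survival genes")
    survival_idx = non_special[: cfg.n_survival_genes]

    lfc = np.zeros(cfg.n_genes)
    mags = rng.uniform(cfg.lfc_low, cfg.lfc_high, cfg.n_informative)
    signs = rng.choice([-1.0, 1.0], cfg.n_informative)
    lfc[informative_idx] = mags * signs

    shifted_mask = np.zeros(cfg.n_genes, dtype=bool)
    shifted_mask[shifted_idx] = True
    shift_sd = _sd_log2(2.0 ** log2_mu, phi)
    shift_amount = np.where(shifted_mask, cfg.shift_location * shift_sd, 0.0)

    def _make_cohort(n: int, cohort: str, shifted_cohort: bool):
        y = rng.binomial(1, cfg.prevalence, n)
        log2_mean = np.tile(log2_mu[:, None], (1, n))
        effect = lfc.copy()
        if shifted_cohort:
            effect = np.where(shifted_mask, 0.0, effect)  # shifted genes don't transfer
            log2_mean += shift_amount[:, None]
        log2_mean[:, y == 1] += effect[:, None]
        mu = 2.0 ** log2_mean
        depth = np.exp(rng.normal(0.0, cfg.depth_sd, n))
        mu = mu * depth[None, :]
        phi_cohort = phi * (cfg.shift_scale ** 2) if shifted_cohort else phi
        phi_used = np.where(shifted_mask, phi_cohort, phi) if shifted_cohort else phi
        counts = _nb_sample(rng, mu, phi_used)
        sample_ids = [f"{cohort}{j:04d}" for j in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame(counts, index=genes, columns=sample_ids), Unit.counts
        )
        return expr, y, sample_ids

    train_expr, y_train, train_ids = _make_cohort(cfg.n_train, "TR", shifted_cohort=False)
    test_expr, y_test, test_ids = _make_cohort(cfg.n_test, "TE", shifted_cohort=True)

    def _survival(expr: ExpressionMatrix, n: int):
        logx = np.log2(expr.values.to_numpy()[survival_idx] + 1.0)
        sd = logx.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (logx - logx.mean(axis=1, keepdims=True)) / sd[:, None]
        risk = z.mean(axis=0) if survival_idx.size else np.zeros(n)
        base = LN2 / cfg.median_os_months
        hazard = base * cfg.survival_hr ** (risk / MEDIAN_SPLIT_GAP)
        t = rng.exponential(1.0 / hazard)
        if 0 < cfg.censor_rate < 1:
            cutoff = np.quantile(t, 1.0 - cfg.censor_rate)
            event = (t <= cutoff).astype(int)
            t = np.minimum(t, cutoff)
        else:
            event = np.ones(n, dtype=int)
        return t, event

    t_train, e_train = _survival(train_expr, cfg.n_train)
    t_test, e_test = _survival(test_expr, cfg.n_test)

    recist_pool_resp = np.array(["CR", "PR"])
    recist_pool_non = np.array(["SD", "PD"])

    def _clinical(ids, y, t, e):
        recist = np.where(
            y == 1,
            recist_pool_resp[rng.integers(0, 2, len(ids))],
            recist_pool_non[rng.integers(0, 2, len(ids))],
        )
        return ClinicalTable(
            pd.DataFrame(
                {
                    "recist": recist,
                    "response": y.astype(int),
                    "os_time": t,
                    "os_event": e,
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )

    truth = SimulationTruth(
        informative_genes={genes[i]: float(lfc[i]) for i in informative_idx},
        shifted_genes={
            genes[i]: {"location_sd": float(cfg.shift_location), "scale": float(cfg.shift_scale)}
            for i in shifted_idx
        },
        survival_genes={genes[i]: float(cfg.survival_hr) for i in survival_idx},
        response_probability=cfg.prevalence,
    )
    return SimulatedData(
        train_counts=train_expr,
        train_clinical=_clinical(train_ids, y_train, t_train, e_train),
        test_counts=test_expr,
        test_clinical=_clinical(test_ids, y_test, t_test, e_test),
        gene_lengths=lengths,
        truth=truth,
    )


def null_config(seed: int = 0, n_genes: int = 200, n: int = 100) -> SimulationConfig:
    """No informative genes, no shift, no survival signal: the calibration null."""
    return SimulationConfig(
        n_genes=n_genes, n_train=n, n_test=n,
        n_informative=0, n_shifted=0, n_survival_genes=0, seed=seed,
    )


def signal_config(seed: int = 0, lfc: float | None = None) -> SimulationConfig:
    """Signal-recovery scenario: 40 informative unshifted + 40 informative
    shifted genes among 2,000, cohorts of 150/80.

    ``lfc`` pins both ends of the effect-size range (e.g. 1.5 for the
    strong-signal variant); default keeps the [0.5, 1.5] range.
    """
    kw = {} if lfc is None else {"lfc_low": lfc, "lfc_high": lfc}
    return SimulationConfig(
        n_genes=2000, n_train=150, n_test=80,
        n_informative=80, n_shifted=40, frac_informative_shifted=1.0,
        shift_location=2.5, seed=seed, **kw,
    )


def shifted_ablation_config(seed: int = 0) -> SimulationConfig:
    """Domain-shift scenario for the DA-on/off ablation.

    Most of the response signal is carried by non-transferable genes (18 of
    24 informative genes are shifted and lose their association in the test
    cohort), with moderate effect sizes so neither model saturates; the DA
    filter's benefit is then visible in held-out AUC.
    """
    return SimulationConfig(
        n_genes=600, n_train=100, n_test=120,
        n_informative=24, lfc_low=0.5, lfc_high=0.9, nb_dispersion=0.3,
        n_shifted=18, frac_informative_shifted=1.0, shift_location=2.5,
        seed=seed,
    )


def worked_fixture(seed: int = 20240917) -> SimulatedData:
    """Tiny deterministic dataset (12 genes, 20 train + 12 test samples).

    Small enough that every downstream statistic can be checked by hand or
    by brute force; shipped as committed files with an oracle-computed
    manifest, and regenerable exactly from this function.
    """
    cfg = SimulationConfig(
        n_genes=12, n_train=20, n_test=12, prevalence=0.4,
        n_informative=3, lfc_low=1.0, lfc_high=2.0,
        n_shifted=2, shift_location=3.0, frac_informative_shifted=0.0,
        n_survival_genes=2, survival_hr=3.0, censor_rate=0.25,
        baseline_log2_mean=(4.0, 8.0), seed=seed,
    )
    return simulate_cohorts(cfg)
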
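"""End-to-end validation studies run against the synthetic generators.

Each function simulates data with known ground truth, pushes it through
the corresponding pipeline stage and returns a summary error or
agreement statistic. They are the package's own correctness experiments
— small enough to run in seconds to minutes on one CPU — and are driven
both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .conversion_stats import (
    anova_tukey_cld,
    sfa_percentages,
    stepwise_conversions,
)
from .fa_model import FattyAcid, Series, parse_fa
from .qpcr_quant import (
    QpcrMeasurement,
    StandardCurve,
    fit_standard_curve,
    normalized_ratios,
)
from .seq_motifs import DEFAULT_MOTIFS, MotifPattern, scan_motifs, translate_orf
from .synthetic_data import (
    CascadeSimConfig,
    QpcrSimConfig,
    SfaSimConfig,
    simulate_cascade_areas,
    simulate_qpcr,
    simulate_sfa_profiles,
)

__all__ = [
    "random_orf",
    "orf_protein_length",
    "noiseless_recovery_error",
    "noisy_recovery_error",
    "edge_case_semantics",
    "qpcr_roundtrip_error",
    "qpcr_mean_coverage",
    "cld_tukey_agreement",
    "sfa_percent_sum_deviation",
    "motif_scan_agreement",
]

_SUBSTRATE = parse_fa("18:4n-3")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_orf(n_bp: int, seed: int) -> str:
    """A random valid ORF (ATG, sense codons, TAA) of ``n_bp`` nucleotides."""
    if n_bp % 3 != 0 or n_bp < 9:
        raise ValueError("ORF length must be a multiple of 3 and >= 9")
    rng = np.random.default_rng(seed)
    inner = rng.choice(_SENSE_CODONS, size=n_bp // 3 - 2)
    return "ATG" + "".join(inner) + "TAA"


def orf_protein_length(n_bp: int, seed: int = 0) -> int:
    """Translate a random ORF of ``n_bp`` and return the protein length."""
    return len(translate_orf(random_orf(n_bp, seed)))


def _random_fractions(rng: np.random.Generator, min_len=1, max_len=9) -> tuple[float, ...]:
    k = int(rng.integers(min_len, max_len + 1))
    return tuple(rng.uniform(0.0, 0.95, size=k))


def noiseless_recovery_error(n_vectors: int = 500, seed: int = 0) -> float:
    """Max |recovered − 100·e_k| over random noiseless cascades (pp).

    The sequential-partition model guarantees exact recovery; any error
    beyond floating-point noise indicates a defect in the statistic.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        fractions = _random_fractions(rng)
        cfg = CascadeSimConfig(
            _SUBSTRATE, fractions, a0=float(rng.uniform(10, 1e4)),
            seed=int(rng.integers(2**31)),
        )
        res = stepwise_conversions(simulate_cascade_areas(cfg), cfg.cascade)
        for r, e in zip(res, fractions):
            worst = max(worst, abs(r.conversion - 100.0 * e))
    return worst


def noisy_recovery_error(
    n_seeds: int = 200, noise_sigma: float = 0.05, n_steps: int = 8, seed: int = 0
) -> float:
    """Worst per-step mean |error| (pp) under multiplicative area noise.

    A single moderate step-fraction vector is drawn once from ``seed``;
    ``n_seeds`` independent noisy tables are simulated and the recovered
    conversions compared with truth. No detection limit is applied, so
    no step is clipped.
    """
    rng = np.random.default_rng(seed)
    fractions = tuple(rng.uniform(0.1, 0.9, size=n_steps))
    errors = np.zeros((n_seeds, n_steps))
    for i in range(n_seeds):
        cfg = CascadeSimConfig(
            _SUBSTRATE, fractions, noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31)),
        )
        res = stepwise_conversions(simulate_cascade_areas(cfg), cfg.cascade)
        errors[i] = [abs(r.conversion - 100.0 * e) for r, e in zip(res, fractions)]
    return float(errors.mean(axis=0).max())


def edge_case_semantics() -> dict[str, object]:
    """Reproduce the qualitative edge rows of a conversion table.

    A step with zero substrate but detectable product converts at 100;
    a fully undetected tail is flagged not-detected — the coexistence of
    100 and N.D. entries in one cascade.
    """
    from .fa_model import build_cascade

    cascade = build_cascade(_SUBSTRATE, _SUBSTRATE.carbons + 8)
    from .conversion_stats import PeakTable

    areas = dict(zip(cascade.members, [50.0, 0.0, 10.0, 0.0, 0.0]))
    res = stepwise_conversions(PeakTable("edge", "t", areas), cascade)
    return {
        "zero_substrate_with_product_pct": res[1].conversion,
        "undetected_tail_is_nd": res[3].not_detected,
    }


_QPCR_CURVES = {
    "target": StandardCurve(slope=-3.4, intercept=38.0, r_squared=1.0),
    "reference": StandardCurve(slope=-3.2, intercept=33.0, r_squared=1.0),
}
_QPCR_TRUTH = {
    "brain": {"target": 8e5, "reference": 4e7},
    "pituitary": {"target": 2e6, "reference": 4e7},
    "liver": {"target": 4e3, "reference": 4e7},
    "muscle": {"target": 4e4, "reference": 4e7},
}


def _run_qpcr_pipeline(cfg: QpcrSimConfig):
    dil, meas = simulate_qpcr(cfg)
    curves = {
        g: fit_standard_curve(list(zip(d["copies"], d["cq"])))
        for g, d in dil.groupby("gene")
    }
    rep_cols = [c for c in meas.columns if c.startswith("cq_rep")]
    ms = [
        QpcrMeasurement(
            r.tissue, r.sex, r.fish_id, r.gene,
            tuple(getattr(r, c) for c in rep_cols),
        )
        for r in meas.itertuples()
    ]
    return normalized_ratios(ms, curves, "target", "reference")


def qpcr_roundtrip_error(seed: int = 0) -> float:
    """Max relative error of recovered ratios in the noiseless round trip."""
    cfg = QpcrSimConfig(_QPCR_CURVES, _QPCR_TRUTH, cq_sd=0.0, seed=seed)
    worst = 0.0
    for r in _run_qpcr_pipeline(cfg):
        truth = _QPCR_TRUTH[r.tissue]["target"] / _QPCR_TRUTH[r.tissue]["reference"]
        worst = max(worst, abs(r.ratio - truth) / truth)
    return worst


def qpcr_mean_coverage(
    n_replicates: int = 500, cq_sd: float = 0.2, fish_per_tissue: int = 4, seed: int = 0
) -> float:
    """Fraction of per-tissue recovered means within 3 SE of truth.

    The SE is the true sampling standard error of the mean ratio under
    the generative model (duplicate-averaged Gaussian Cq noise mapped
    through both standard curves), so the check measures the bias and
    scale of the quantification pipeline rather than the small-sample
    behaviour of an SE estimate.
    """
    # per-fish log10-ratio noise sd
    s2 = sum(
        (cq_sd / math.sqrt(2) / abs(curve.slope)) ** 2
        for curve in _QPCR_CURVES.values()
    )
    ln10_var = (math.log(10.0) ** 2) * s2
    # lognormal mean/variance of the per-fish multiplicative factor 10^delta
    factor_mean = math.exp(ln10_var / 2)
    factor_sd = math.sqrt(math.exp(ln10_var) * (math.exp(ln10_var) - 1.0))
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_replicates):
        cfg = QpcrSimConfig(
            _QPCR_CURVES, _QPCR_TRUTH, cq_sd=cq_sd,
            fish_per_tissue=fish_per_tissue, seed=int(rng.integers(2**31)),
        )
        ratios = _run_qpcr_pipeline(cfg)
        by_tissue: dict[str, list[float]] = {}
        for r in ratios:
            by_tissue.setdefault(r.tissue, []).append(r.ratio)
        for tissue, vals in by_tissue.items():
            truth = _QPCR_TRUTH[tissue]["target"] / _QPCR_TRUTH[tissue]["reference"]
            se_true = truth * factor_sd / math.sqrt(len(vals))
            centre = truth * factor_mean  # small lognormal bias of the mean
            hits += abs(float(np.mean(vals)) - centre) <= 3 * se_true
            total += 1
    return hits / total


def cld_tukey_agreement(n_datasets: int = 100, alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of random datasets whose compact letters match every
    pairwise Tukey decision (share a letter ⇔ p > alpha)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_datasets):
        n_groups = int(rng.integers(2, 7))
        n = int(rng.integers(3, 7))
        spread = float(rng.uniform(0.2, 5.0))
        data = {
            f"g{i}": rng.uniform(0, 10) + rng.normal(0, spread, size=n)
            for i in range(n_groups)
        }
        vc = anova_tukey_cld(data, alpha=alpha)
        ok = True
        groups = list(data)
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                shares = bool(set(vc.letters[g1]) & set(vc.letters[g2]))
                if shares != (vc.tukey_p[tuple(sorted((g1, g2)))] > alpha):
                    ok = False
        agree += ok
    return agree / n_datasets


def sfa_percent_sum_deviation(n_profiles: int = 50, seed: int = 0) -> float:
    """Max |sum of SFA percentages − 100| over simulated replicate profiles."""
    baseline = {
        FattyAcid(24, 0, Series.SATURATED): 1.2,
        FattyAcid(26, 0, Series.SATURATED): 23.5,
        FattyAcid(28, 0, Series.SATURATED): 0.9,
        FattyAcid(30, 0, Series.SATURATED): 0.2,
        FattyAcid(32, 0, Series.SATURATED): 0.04,
    }
    cfg = SfaSimConfig(
        baseline,
        {"elovl4a": {FattyAcid(28, 0, Series.SATURATED): 4.0}},
        n_replicates=max(2, n_profiles // 2),
        noise_cv=0.2,
        seed=seed,
    )
    worst = 0.0
    for table in simulate_sfa_profiles(cfg):
        total = sum(sfa_percentages(table).percents.values())
        worst = max(worst, abs(total - 100.0))
    return worst


def motif_scan_agreement(n_proteins: int = 1000, seed: int = 0) -> float:
    """Fraction of random proteins where the positional scanner matches an
    exhaustive regex-lookahead comparator for every default motif."""
    rng = np.random.default_rng(seed)
    patterns = list(DEFAULT_MOTIFS) + [MotifPattern("er_anywhere", "RXKXX")]
    agree = 0
    for _ in range(n_proteins):
        protein = "".join(rng.choice(_AA20, size=int(rng.integers(5, 400))))
        ok = True
        for pat in patterns:
            rx = re.compile(f"(?=({pat.pattern.replace('X', '.')}))")
            expected = [m.start() + 1 for m in rx.finditer(protein)]
            got = [h.start for h in scan_motifs(protein, [pat])]
            if got != expected:
                ok = False
        agree += ok
    return agree / n_proteins
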
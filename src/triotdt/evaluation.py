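"""Type-I error, power, and QQ summaries over replicated trio simulations.

Two study designs are orchestrated here:

* a *type-I* study: one fixed rare-variant panel, replicated null cohorts of
  random trios, each error condition injected into every cohort, gene-level
  tests pooled across replicates;
* a *power* study: every gene is its own replicate — a one-gene panel with a
  fraction of its variants causal, an affected cohort ascertained under the
  logistic disease model, and the gene-level rejection rate read as power.

Within a replicate all error conditions are injected with the same seed, so
the uniform draws are shared and the flip sets at increasing rates are
nested: condition contrasts (inflation in r1, power loss in r1) are coupled
comparisons on identical cohorts, not independent simulations.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TrioCohort, simulate_affected_trios, simulate_trios
from .errors import ErrorSpec, inject_errors
from .genes import gene_tdt
from .panel import DiseaseModel, sample_panel
from .transmission import tally

__all__ = [
    "QQSummary",
    "RateEstimate",
    "qq_summary",
    "estimate_rate",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
]

NO_ERROR = "none"


@dataclasses.dataclass
class QQSummary:
    """Expected-vs-observed -log10 p-value quantiles with a pointwise band.

    Rank i (1-based, i = 1 the *largest* p-value) has expected quantile
    -log10 of the median of the i-th-from-top uniform order statistic; the
    band brackets that order statistic's central ``band_level`` mass. All
    sequences run in increasing -log10 order.
    """

    n_tests: int
    expected: np.ndarray
    observed: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    band_level: float = 0.95

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_tests + 1),
                "expected": self.expected,
                "observed": self.observed,
                "band_lower": self.band_lower,
                "band_upper": self.band_upper,
            }
        )


@dataclasses.dataclass
class RateEstimate:
    """Rejection fraction at a nominal level with an exact binomial 95% CI."""

    alpha: float
    n_tests: int
    n_rejections: int
    rate: float
    ci_low: float
    ci_high: float


def qq_summary(p_values, band_level: float = 0.95) -> QQSummary:
    """QQ summary of p-values against the uniform null.

    Under the null of n independent Uniform(0,1) p-values, the i-th smallest
    is Beta(i, n-i+1); expected quantiles are the medians of these laws and
    the band their central ``band_level`` mass — the standard pointwise
    envelope of a QQ plot. Zero p-values are floored at the smallest
    positive float before taking -log10.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < band_level < 1.0:
        raise ValueError("band_level must lie in (0, 1)")
    n = p.size
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # i-th smallest p-value, listed from largest (rank 1) to smallest (rank n)
    i = np.arange(n, 0, -1)
    a, b = i, n - i + 1
    expected = -np.log10(stats.beta.ppf(0.5, a, b))
    lo_tail = (1.0 - band_level) / 2.0
    band_upper = -np.log10(stats.beta.ppf(lo_tail, a, b))
    band_lower = -np.log10(stats.beta.ppf(1.0 - lo_tail, a, b))
    observed = -np.log10(np.sort(p)[::-1])
    return QQSummary(n, expected, observed, band_lower, band_upper, band_level)


def estimate_rate(p_values, alpha: float = 0.05) -> RateEstimate:
    """Fraction of tests rejected at ``alpha``, with exact (Clopper-Pearson)
    95% confidence interval."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k = int((p <= alpha).sum())
    n = int(p.size)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return RateEstimate(alpha, n, k, k / n, float(ci.low), float(ci.high))


@dataclasses.dataclass
class ExperimentConfig:
    """Full configuration of a replicated simulation study."""

    mode: str = "type1"  # "type1" or "power"
    n_genes: int = 500
    variants_per_gene: object = ("poisson", 40.0)
    maf_cap: float = 0.05
    n_eff: int = 1000
    n_trios: int = 100
    n_replicates: int = 20
    conditions: Sequence[ErrorSpec] = ()
    alpha: float = 0.05
    # power-study disease model
    beta: float = float(np.log(4.0))
    causal_fraction: float = 0.30
    baseline_prevalence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("type1", "power"):
            raise ValueError("mode must be 'type1' or 'power'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def digest_payload(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = [c.label() for c in self.conditions]
        d["variants_per_gene"] = repr(self.variants_per_gene)
        return d


@dataclasses.dataclass
class ExperimentResult:
    config: ExperimentConfig
    totals: pd.DataFrame                 # per condition: T, U, pct, n_excluded
    gene_tables: dict                    # condition -> per-gene DataFrame
    gene_pvalues: dict                   # condition -> pooled p-value array
    rates: dict                          # condition -> RateEstimate
    qq: dict                             # condition -> QQSummary

    def save(self, outdir) -> None:
        """Write totals, per-gene tables, QQ tables, rates and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.totals.to_csv(outdir / "totals.tsv", sep="\t", index=True)
        rates = pd.DataFrame(
            {lab: dataclasses.asdict(r) for lab, r in self.rates.items()}
        ).T
        rates.index.name = "condition"
        rates.to_csv(outdir / "rejection_rates.tsv", sep="\t")
        for lab in self.gene_tables:
            safe = lab.replace(" ", "_").replace(";", "").replace("=", "")
            self.gene_tables[lab].to_csv(
                outdir / f"genes_{safe}.tsv", sep="\t", index=False
            )
            self.qq[lab].frame().to_csv(outdir / f"qq_{safe}.tsv", sep="\t", index=False)
        manifest = {
            "config": self.config.digest_payload(),
            "conditions": list(self.gene_tables),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _condition_labels(conditions: Sequence[ErrorSpec]) -> list[str]:
    return [NO_ERROR] + [c.label() for c in conditions]


def _observed_cohorts(cohort: TrioCohort, conditions, inject_seed: int):
    """The unperturbed cohort plus one injected copy per condition, all
    sharing the injection seed (coupled flips)."""
    yield NO_ERROR, cohort
    for spec in conditions:
        yield spec.label(), inject_errors(cohort, spec, seed=inject_seed)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate -> inject -> tally -> test -> summarise, per condition.

    Deterministic given the config (same config twice gives bit-identical
    results). Stage failures propagate with the replicate and condition
    identity attached.
    """
    master = np.random.default_rng(config.seed)
    seeds = master.integers(2**31, size=2 + 2 * config.n_replicates)
    labels = _condition_labels(config.conditions)
    gene_frames: dict = {lab: [] for lab in labels}
    totals = {lab: np.zeros(3, dtype=float) for lab in labels}  # T, U, n_excluded

    if config.mode == "type1":
        panel = sample_panel(
            config.n_genes,
            config.variants_per_gene,
            maf_cap=config.maf_cap,
            seed=int(seeds[0]),
            n_eff=config.n_eff,
        )
    else:
        model = DiseaseModel(config.causal_fraction, config.beta, config.baseline_prevalence)

    for rep in range(config.n_replicates):
        sim_seed = int(seeds[2 + 2 * rep])
        inj_seed = int(seeds[3 + 2 * rep])
        try:
            if config.mode == "type1":
                cohort = simulate_trios(panel, config.n_trios, seed=sim_seed)
            else:
                # one gene per replicate, with its own affected cohort
                gpanel = sample_panel(
                    1,
                    config.variants_per_gene,
                    maf_cap=config.maf_cap,
                    seed=sim_seed,
                    n_eff=config.n_eff,
                ).attach_disease_model(model, seed=sim_seed)
                cohort = simulate_affected_trios(
                    gpanel, model, config.n_trios, seed=sim_seed
                )
            for lab, obs in _observed_cohorts(cohort, config.conditions, inj_seed):
                counts = tally(obs, layer="observed")
                genes = gene_tdt(counts, obs.panel)
                genes.insert(0, "replicate", rep)
                gene_frames[lab].append(genes)
                T, U = counts.totals
                totals[lab] += (T, U, counts.n_excluded)
        except Exception as exc:  # annotate with stage identity
            raise RuntimeError(
                f"replicate {rep} ({config.mode}) failed: {exc}"
            ) from exc

    gene_tables = {lab: pd.concat(fs, ignore_index=True) for lab, fs in gene_frames.items()}
    gene_pvalues = {lab: t["p_value"].to_numpy() for lab, t in gene_tables.items()}
    rates = {lab: estimate_rate(pv, config.alpha) for lab, pv in gene_pvalues.items()}
    qq = {lab: qq_summary(pv) for lab, pv in gene_pvalues.items()}
    totals_df = pd.DataFrame(
        {lab: dict(T=v[0], U=v[1], n_excluded=v[2]) for lab, v in totals.items()}
    ).T
    totals_df["pct_transmitted"] = [
        round(100 * t / (t + u)) if t + u else np.nan
        for t, u in zip(totals_df["T"], totals_df["U"])
    ]
    totals_df.index.name = "condition"
    return ExperimentResult(config, totals_df, gene_tables, gene_pvalues, rates, qq)
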
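"""Bayesian haplogroup prediction from Y-STR allele frequencies.

A :class:`HaplogroupFrequencyModel` stores, for each candidate haplogroup,
per-locus allele frequencies (for DYS385a/b: frequencies of the unordered
pair). Prediction is naive-Bayes: the likelihood of a haplotype under
haplogroup g is the product over loci of the smoothed allele frequency,
posteriors combine likelihoods with the (default equal) priors, and a
fitness score in [0, 100] is reported as the per-locus-normalized
geometric mean

    score = 100 * ( prod_l f_g,l(a_l) / max_a f_g,l(a) )^(1/L)

for the best haplogroup — 100 means every allele is modal for that
haplogroup. A call is UNASSIGNED unless score >= min_score (default 40)
and posterior >= min_prob (default 0.95).

The model shipped with the simulator is a synthetic fixture estimated
from simulated cohorts with known founder labels; it makes no claim to
reproduce any published predictor's internal tables — the assignment
contract (thresholds, assign/unassign behavior) is the specified part.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import AlleleCall, Cohort, SampleRecord
from .panel import MULTI_COPY_LOCUS

UNASSIGNED = "UNASSIGNED"


def _pair_key(alleles: tuple[AlleleCall, ...]) -> str:
    return ",".join(str(a) for a in sorted(alleles))


@dataclass(frozen=True)
class HaplogroupFrequencyModel:
    """Per-haplogroup, per-locus allele (or DYS385 pair) frequencies.

    ``frequencies[haplogroup][locus]`` maps an allele string (or
    canonical "a,b" pair string for DYS385a/b) to its smoothed frequency.
    Frequencies at a locus sum to 1 over the locus's observed support;
    alleles outside the support fall back to ``pseudocount`` (and, for an
    unseen DYS385 pair, to the product of single-allele marginals).
    """

    frequencies: dict[str, dict[str, dict[str, float]]]
    priors: dict[str, float]
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        total = sum(self.priors.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"priors must sum to 1, got {total}")
        if set(self.priors) != set(self.frequencies):
            raise ValueError("priors and frequency tables name different haplogroups")

    @property
    def haplogroups(self) -> list[str]:
        return sorted(self.frequencies)

    def loci(self) -> list[str]:
        first = next(iter(self.frequencies.values()))
        return list(first)

    def with_priors(self, priors: dict[str, float]) -> "HaplogroupFrequencyModel":
        return HaplogroupFrequencyModel(self.frequencies, priors, self.pseudocount)

    # -- frequency lookup ---------------------------------------------------

    def allele_frequency(self, hg: str, locus: str, alleles: tuple[AlleleCall, ...]) -> float:
        table = self.frequencies[hg][locus]
        if locus == MULTI_COPY_LOCUS:
            key = _pair_key(alleles)
            if key in table:
                return table[key]
            # fallback: product of single-allele marginals from the pair table
            marg: dict[str, float] = {}
            for pair, f in table.items():
                for a in pair.split(","):
                    marg[a] = marg.get(a, 0.0) + f / 2.0
            a1, a2 = str(min(alleles)), str(max(alleles))
            f = marg.get(a1, self.pseudocount) * marg.get(a2, self.pseudocount)
            if a1 != a2:
                f *= 2.0
            return max(f, self.pseudocount**2)
        return table.get(str(alleles[0]), self.pseudocount)

    def max_frequency(self, hg: str, locus: str) -> float:
        return max(self.frequencies[hg][locus].values())

    # -- construction and serialization -------------------------------------

    @classmethod
    def from_labeled_cohort(
        cls,
        cohort: Cohort,
        labels: dict[str, str],
        pseudocount: float = 1e-3,
        priors: dict[str, float] | None = None,
    ) -> "HaplogroupFrequencyModel":
        """Estimate a model from a cohort with known haplogroup labels.

        Counting-method frequencies with additive (pseudocount) smoothing
        over each locus's observed support, so each locus distribution
        sums to 1.
        """
        groups: dict[str, list[SampleRecord]] = {}
        for s in cohort.samples:
            groups.setdefault(labels[s.sample_id], []).append(s)
        names = cohort.locus_names
        support: dict[str, set[str]] = {n: set() for n in names}
        for s in cohort.samples:
            for n in names:
                key = _pair_key(s.calls[n]) if n == MULTI_COPY_LOCUS else str(s.calls[n][0])
                support[n].add(key)
        freqs: dict[str, dict[str, dict[str, float]]] = {}
        for hg, members in groups.items():
            freqs[hg] = {}
            for n in names:
                counts = {k: pseudocount for k in support[n]}
                for s in members:
                    key = _pair_key(s.calls[n]) if n == MULTI_COPY_LOCUS else str(s.calls[n][0])
                    counts[key] += 1.0
                total = sum(counts.values())
                freqs[hg][n] = {k: c / total for k, c in counts.items()}
        if priors is None:
            priors = {hg: 1.0 / len(freqs) for hg in freqs}
        return cls(freqs, priors, pseudocount)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pseudocount": self.pseudocount,
            "priors": self.priors,
            "frequencies": self.frequencies,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "HaplogroupFrequencyModel":
        payload = json.loads(Path(path).read_text())
        return cls(payload["frequencies"], payload["priors"], payload["pseudocount"])


@dataclass(frozen=True)
class HaplogroupCall:
    best: str  # haplogroup name or UNASSIGNED
    posterior: float
    score: float
    per_haplogroup: dict[str, tuple[float, float]] = field(default_factory=dict)


def predict_haplogroup(
    sample: SampleRecord,
    model: HaplogroupFrequencyModel,
    min_score: float = 40.0,
    min_prob: float = 0.95,
    min_loci: int = 15,
) -> HaplogroupCall:
    """Classify one haplotype; UNASSIGNED below either threshold."""
    loci = [n for n in model.loci() if n in sample.calls]
    if len(loci) < min_loci:
        raise ValueError(
            f"sample {sample.sample_id}: only {len(loci)} loci overlap the model "
            f"(minimum {min_loci})"
        )
    hgs = model.haplogroups
    loglik = {}
    for hg in hgs:
        loglik[hg] = sum(
            math.log(model.allele_frequency(hg, n, sample.calls[n])) for n in loci
        )
    m = max(loglik.values())
    weights = {hg: model.priors[hg] * math.exp(loglik[hg] - m) for hg in hgs}
    z = sum(weights.values())
    posteriors = {hg: w / z for hg, w in weights.items()}
    best = max(hgs, key=lambda h: (posteriors[h], h))

    log_fit = sum(
        math.log(model.allele_frequency(best, n, sample.calls[n]))
        - math.log(model.max_frequency(best, n))
        for n in loci
    )
    score = 100.0 * math.exp(log_fit / len(loci))
    score = min(score, 100.0)

    per = {hg: (math.exp(loglik[hg] - m), posteriors[hg]) for hg in hgs}
    assigned = score >= min_score and posteriors[best] >= min_prob
    return HaplogroupCall(
        best=best if assigned else UNASSIGNED,
        posterior=posteriors[best],
        score=score,
        per_haplogroup=per,
    )


def batch_predict(
    cohort: Cohort,
    model: HaplogroupFrequencyModel,
    min_score: float = 40.0,
    min_prob: float = 0.95,
    min_loci: int = 15,
    sample_ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each sample (optionally a subset) and tabulate by region.

    Returns ``(calls, proportions)``: one row per sample with best call,
    score and posterior; and region x haplogroup percentages among
    assigned samples (plus an ``n_assigned``/``n_total`` accounting, with
    an ``ALL`` row for the overall proportions).
    """
    if sample_ids is not None:
        cohort = cohort.subset(sample_ids)
    rows = []
    for s in cohort.samples:
        call = predict_haplogroup(s, model, min_score, min_prob, min_loci)
        rows.append(
            {
                "sample_id": s.sample_id,
                "region": s.region,
                "population": s.population,
                "best": call.best,
                "score": call.score,
                "posterior": call.posterior,
            }
        )
    calls = pd.DataFrame(
        rows, columns=["sample_id", "region", "population", "best", "score", "posterior"]
    )
    if calls.empty:
        return calls, pd.DataFrame()

    def _props(df: pd.DataFrame) -> dict:
        assigned = df[df["best"] != UNASSIGNED]
        out = {"n_total": len(df), "n_assigned": len(assigned)}
        if len(assigned):
            pct = assigned["best"].value_counts(normalize=True) * 100.0
            out.update(pct.to_dict())
        return out

    blocks = {region: _props(df) for region, df in calls.groupby("region")}
    blocks["ALL"] = _props(calls)
    proportions = pd.DataFrame.from_dict(blocks, orient="index").fillna(0.0)
    return calls, proportions
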
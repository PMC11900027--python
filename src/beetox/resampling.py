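"""Resampling-based robustness diagnostics for the DE analysis.

Two diagnostics:

* **Replicate-balance subsampling** — chronic and control groups carry more
  replicates (10) than acute groups (8), so the chronic-vs-control DE
  analysis is repeatedly rerun on unique random subsets of eight replicates
  per group.  The distribution of DE gene counts yields an add-one
  permutation p-value for whether each acute contrast's DE count could be an
  artefact of its smaller sample size.
* **Colony-confounding resampling** — control and treated samples are drawn
  either from the same random half of the source colonies (matched: genetic
  background controlled) or from complementary halves (mismatched: colony
  confounded with treatment), the DE model is rerun without the colony
  covariate, and the two DE-count distributions are compared
  (median, skewness, two-sample KS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .config import CONTROL, DESettings
from .contrasts import ks_two_sample
from .de import de_pipeline


@dataclass(frozen=True)
class SubsampleConfig:
    n_iterations: int = 50
    target_n: int = 8
    unique_subsets: bool = True
    seed: int = 0


@dataclass(frozen=True)
class ConfoundConfig:
    n_iterations: int = 100
    colonies_per_arm: int = 5
    matched: bool = True
    seed: int = 0


@dataclass
class DistributionSummary:
    """A distribution of DE gene counts across resampling iterations."""

    de_counts: np.ndarray
    median: float
    skewness: float
    p_values: dict[str, float] = field(default_factory=dict)
    subset_signatures: list[tuple] = field(default_factory=list)

    @classmethod
    def from_counts(cls, counts, **kw) -> "DistributionSummary":
        arr = np.asarray(counts, dtype=int)
        if (arr < 0).any():
            raise ValueError("DE counts must be non-negative")
        if len(arr) >= 3 and arr.var() > 0:
            from .contrasts import skewness as _skew

            skew = _skew(arr)
        else:
            skew = float("nan")
        return cls(de_counts=arr, median=float(np.median(arr)), skewness=skew, **kw)


def _de_count(counts, meta, contrast, settings, include_colony):
    tables = de_pipeline(
        counts, meta, settings, contrasts=[contrast], include_colony=include_colony
    )
    return int(tables[contrast]["significant"].sum())


def balanced_subsample_de(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    acute_contrasts: list[str],
    config: SubsampleConfig = SubsampleConfig(),
    settings: DESettings = DESettings(),
    chronic_contrasts: list[str] | None = None,
) -> dict[str, DistributionSummary]:
    """Rerun chronic DE analyses at the acute groups' replicate number.

    For every chronic contrast, each iteration draws a fresh (never
    previously used, when ``unique_subsets``) joint subset of ``target_n``
    control and ``target_n`` chronic samples, reruns the full DE pipeline
    (filter, size factors, dispersion, Wald with treatment + colony design),
    and records the number of FDR-significant genes.  Each acute contrast's
    DE count — computed once on the full design — is then compared against
    the distribution with an add-one permutation p-value
    ``(1 + #{iterations >= acute count}) / (n_iterations + 1)``.
    """
    if chronic_contrasts is None:
        chronic_contrasts = sorted(
            t for t in meta["treatment"].unique() if t.endswith("_chronic")
        )
    acute_counts = {
        a: _de_count(counts, meta, a, settings, include_colony=True)
        for a in acute_contrasts
    }
    out: dict[str, DistributionSummary] = {}
    for ci, chronic in enumerate(chronic_contrasts):
        rng = np.random.default_rng([int(config.seed), ci])
        ctrl_ids = meta.loc[meta["treatment"] == CONTROL, "sample_id"].to_numpy()
        trt_ids = meta.loc[meta["treatment"] == chronic, "sample_id"].to_numpy()
        for name, ids in (("control", ctrl_ids), (chronic, trt_ids)):
            if len(ids) < config.target_n:
                raise ValueError(
                    f"group {name!r} has {len(ids)} replicates < target_n={config.target_n}"
                )
        n_subsets = comb(len(ctrl_ids), config.target_n) * comb(len(trt_ids), config.target_n)
        if config.unique_subsets and config.n_iterations > n_subsets:
            raise ValueError(
                f"unique_subsets infeasible: {config.n_iterations} iterations but only "
                f"{n_subsets} distinct joint subsets exist"
            )
        seen: set[tuple] = set()
        de_counts = []
        signatures = []
        for _ in range(config.n_iterations):
            while True:
                sub_ctrl = tuple(sorted(rng.choice(ctrl_ids, config.target_n, replace=False)))
                sub_trt = tuple(sorted(rng.choice(trt_ids, config.target_n, replace=False)))
                sig = (sub_ctrl, sub_trt)
                if not config.unique_subsets or sig not in seen:
                    break
            seen.add(sig)
            keep = list(sub_ctrl + sub_trt)
            sub_meta = meta.loc[meta["sample_id"].isin(keep)]
            assert set(sub_meta["treatment"]) == {CONTROL, chronic}
            de_counts.append(
                _de_count(counts[keep], sub_meta, chronic, settings, include_colony=True)
            )
            signatures.append(sig)
        arr = np.asarray(de_counts)
        p_values = {
            a: (1 + int((arr >= acute_counts[a]).sum())) / (config.n_iterations + 1)
            for a in acute_contrasts
        }
        out[chronic] = DistributionSummary.from_counts(
            arr, p_values=p_values, subset_signatures=signatures
        )
    return out


def colony_confound_resample(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    treatment: str,
    config: ConfoundConfig = ConfoundConfig(),
    settings: DESettings = DESettings(),
) -> tuple[DistributionSummary, DistributionSummary, tuple[float, float]]:
    """Matched vs mismatched colony resampling of a treatment-vs-control DE run.

    Matched iterations draw both arms' samples from the same random half of
    the colonies and keep the colony blocking factor in the DE model (the
    genetic background is controlled, and modelling it removes colony
    variance from the residual dispersion).  Mismatched iterations draw the
    control arm from one colony half and the treated arm from the
    complementary half: colony is completely confounded with treatment by
    construction, the covariate cannot be fitted, and it is dropped.
    Returns the two DE-count distributions and the two-sample KS statistic
    comparing them.
    """
    matched_summary = confound_resample_mode(
        counts, meta, treatment, config, settings, matched=True
    )
    mismatched_summary = confound_resample_mode(
        counts, meta, treatment, config, settings, matched=False
    )
    ks = ks_two_sample(matched_summary.de_counts, mismatched_summary.de_counts)
    return matched_summary, mismatched_summary, ks


def confound_resample_mode(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    treatment: str,
    config: ConfoundConfig = ConfoundConfig(),
    settings: DESettings = DESettings(),
    matched: bool = True,
) -> DistributionSummary:
    """One arm of the colony-confounding diagnostic (matched or mismatched).

    Matched mode needs ``colonies_per_arm`` colonies shared by both arms
    (with every colony selected, the draws reduce to the full design and the
    distribution is degenerate); mismatched mode needs twice that many.
    """
    ctrl = meta.loc[meta["treatment"] == CONTROL]
    trt = meta.loc[meta["treatment"] == treatment]
    if trt.empty or ctrl.empty:
        raise ValueError("both arms must be non-empty")
    colonies = np.asarray(sorted(set(ctrl["colony"]) & set(trt["colony"])))
    needed = config.colonies_per_arm if matched else 2 * config.colonies_per_arm
    if len(colonies) < needed:
        raise ValueError(
            f"need >= {needed} colonies with samples in both arms; found {len(colonies)}"
        )
    rng = np.random.default_rng([int(config.seed), 17, int(matched)])
    de_counts = []
    for _ in range(config.n_iterations):
        perm = rng.permutation(colonies)
        half_a = set(perm[: config.colonies_per_arm])
        if matched:
            half_b = half_a
        else:
            half_b = set(perm[config.colonies_per_arm : 2 * config.colonies_per_arm])
        keep_ctrl = ctrl.loc[ctrl["colony"].isin(half_a), "sample_id"]
        keep_trt = trt.loc[trt["colony"].isin(half_b), "sample_id"]
        keep = keep_ctrl.to_list() + keep_trt.to_list()
        sub_meta = meta.loc[meta["sample_id"].isin(keep)]
        assert set(sub_meta["treatment"]) == {CONTROL, treatment}
        de_counts.append(
            _de_count(counts[keep], sub_meta, treatment, settings, include_colony=matched)
        )
    return DistributionSummary.from_counts(de_counts)
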
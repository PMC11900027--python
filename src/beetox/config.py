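"""Configuration objects for the synthetic study design and the DE engine.

The default :class:`SynthConfig` emulates the design of a microcolony
pesticide-exposure experiment: ten source colonies, a control plus three
compounds (acetamiprid, clothianidin, sulfoxaflor) each applied under a
chronic (12-day low-concentration) and an acute (48-hour high-concentration)
scheme, with ten biological replicates for control/chronic groups and eight
for acute groups (64 samples in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

COMPOUNDS = ("acetamiprid", "clothianidin", "sulfoxaflor")
SCHEMES = ("chronic", "acute")
CONTROL = "control"


def treatment_label(compound: str, scheme: str) -> str:
    return f"{compound}_{scheme}"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic count/survival/intake generator.

    Counts are negative binomial with a mean model
    ``mu = library_size * softmax(baseline + colony effect + true log2FC)``
    and a dispersion trend ``alpha(mu) = alpha0 + alpha1 / mu``.  Designated
    differentially expressed (DE) genes additionally receive Gaussian
    replicate-level noise on the log2-mean scale; for acute samples the noise
    standard deviation is multiplied by ``acute_extra_sd_factor`` so that
    VST-scale replicate SDs are directly controllable.
    """

    n_genes: int = 2000
    colonies: int = 10
    replicates_chronic_control: int = 10
    replicates_acute: int = 8
    compounds: Sequence[str] = COMPOUNDS
    library_size_range: tuple[float, float] = (5e6, 1.5e7)
    baseline_log2_mean: tuple[float, float] = (5.0, 1.5)  # (location, scale)
    # designated DE genes start from lower constitutive expression (strongly
    # induced stress/detox genes are rarely high-baseline), which also keeps
    # their induced share of the library realistic
    de_baseline_log2_mean: tuple[float, float] = (1.5, 0.8)
    dispersion_trend: tuple[float, float] = (0.02, 2.0)  # alpha0, alpha1
    colony_effect_sd: float = 0.25  # log2 scale
    # shared-acute DE set: mostly upregulated, large amplitudes
    shared_acute_set_size: int = 61
    acute_up_fraction: float = 0.91
    specific_acute_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"acetamiprid": 30, "clothianidin": 60, "sulfoxaflor": 8}
    )
    # shared-chronic DE set: a few strongly downregulated immune-like genes
    shared_chronic_set_size: int = 12
    chronic_n_strong_down: int = 1
    chronic_strong_down_lfc: float = -5.0  # 32-fold down
    chronic_down_fraction: float = 0.8
    specific_chronic_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"acetamiprid": 10, "clothianidin": 40, "sulfoxaflor": 8}
    )
    lfc_magnitude_range: tuple[float, float] = (1.2, 2.8)
    amplitude_ratio_acute_over_chronic: float = 2.7
    replicate_noise_sd: float = 0.9  # log2 scale, DE genes only
    acute_extra_sd_factor: float = 1.2
    seed: int = 0

    # -- derived ---------------------------------------------------------
    @property
    def treatments(self) -> list[str]:
        out = [CONTROL]
        for compound in self.compounds:
            for scheme in SCHEMES:
                out.append(treatment_label(compound, scheme))
        return out

    @property
    def n_samples(self) -> int:
        n_chronic_groups = 1 + len(self.compounds)  # control + chronic groups
        return (
            n_chronic_groups * self.replicates_chronic_control
            + len(self.compounds) * self.replicates_acute
        )

    def replicates_for(self, treatment: str) -> int:
        if treatment.endswith("_acute"):
            return self.replicates_acute
        return self.replicates_chronic_control

    def total_de_genes(self) -> int:
        return (
            self.shared_acute_set_size
            + sum(self.specific_acute_set_sizes.get(c, 0) for c in self.compounds)
            + self.shared_chronic_set_size
            + sum(self.specific_chronic_set_sizes.get(c, 0) for c in self.compounds)
        )

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.colonies <= 0:
            raise ValueError("colonies must be positive")
        if self.replicates_chronic_control <= 0 or self.replicates_acute <= 0:
            raise ValueError("replicate counts must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive with lo <= hi")
        a0, a1 = self.dispersion_trend
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion trend parameters must be non-negative")
        if self.colony_effect_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("effect SDs must be non-negative")
        if not 0.0 <= self.acute_up_fraction <= 1.0:
            raise ValueError("acute_up_fraction must be in [0, 1]")
        if not 0.0 <= self.chronic_down_fraction <= 1.0:
            raise ValueError("chronic_down_fraction must be in [0, 1]")
        if self.chronic_strong_down_lfc > 0:
            raise ValueError("chronic_strong_down_lfc must be negative or zero")
        if self.amplitude_ratio_acute_over_chronic <= 0:
            raise ValueError("amplitude_ratio_acute_over_chronic must be positive")
        if self.acute_extra_sd_factor <= 0:
            raise ValueError("acute_extra_sd_factor must be positive")
        if min(self.shared_acute_set_size, self.shared_chronic_set_size) < 0:
            raise ValueError("set sizes must be non-negative")
        if self.total_de_genes() > self.n_genes:
            raise ValueError(
                f"designated DE sets ({self.total_de_genes()} genes) exceed n_genes={self.n_genes}"
            )

    @classmethod
    def null(cls, n_genes: int = 2000, seed: int = 0, **overrides) -> "SynthConfig":
        """A fully null configuration: no treatment, colony, or replicate effects.

        Every gene is a null gene, which is the reference condition for
        p-value calibration checks of the DE engine.
        """
        base = cls(
            n_genes=n_genes,
            seed=seed,
            colony_effect_sd=0.0,
            replicate_noise_sd=0.0,
            shared_acute_set_size=0,
            shared_chronic_set_size=0,
            chronic_n_strong_down=0,
            specific_acute_set_sizes={},
            specific_chronic_set_sizes={},
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def scaled_down(cls, n_genes: int = 400, seed: int = 0, **overrides) -> "SynthConfig":
        """A 400-gene design with proportionally scaled DE sets.

        Used where the full 2000-gene design would be wasteful, e.g. inside
        resampling diagnostics that refit the DE model hundreds of times.
        """
        base = cls(
            n_genes=n_genes,
            seed=seed,
            shared_acute_set_size=15,
            specific_acute_set_sizes={"acetamiprid": 8, "clothianidin": 15, "sulfoxaflor": 2},
            shared_chronic_set_size=4,
            chronic_n_strong_down=1,
            specific_chronic_set_sizes={"acetamiprid": 3, "clothianidin": 10, "sulfoxaflor": 2},
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def colony_stress(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """Conditions for the colony-confounding diagnostic.

        Twenty source colonies (one sample per colony per treatment, so
        colony halves of ten can be compared), strong per-gene colony
        effects (SD 1.5 on log2 scale), and the scaled-down DE sets.  Under
        these conditions a colony-mismatched control-vs-treatment comparison
        is masked by genetic background while a colony-matched comparison is
        not.
        """
        base = cls.scaled_down(
            seed=seed,
            colonies=20,
            replicates_chronic_control=20,
            colony_effect_sd=1.5,
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class DESettings:
    """Tuning knobs of the DE engine.

    ``min_count``/``min_samples`` reproduce the "count of at least 10 in at
    least 8 samples" expression filter; ``fdr_alpha`` is the
    Benjamini-Hochberg significance cut-off.
    """

    min_count: int = 10
    min_samples: int = 8
    fdr_alpha: float = 0.05
    dispersion_floor: float = 0.01
    dispersion_cap: float = 10.0
    vst_pseudocount: float = 1.0
    max_irls_iter: int = 50
    irls_tol: float = 1e-8

    def validate(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.dispersion_floor <= 0 or self.dispersion_cap <= self.dispersion_floor:
            raise ValueError("need 0 < dispersion_floor < dispersion_cap")
        if self.vst_pseudocount <= 0:
            raise ValueError("vst_pseudocount must be positive")
        if self.max_irls_iter < 1 or self.irls_tol <= 0:
            raise ValueError("invalid IRLS settings")
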
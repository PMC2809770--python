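"""Configuration for the synthetic data generator."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import yaml

__all__ = ["SimulationConfig"]

# JC-corrected divergence is undefined at p >= 0.75; the corrected value
# diverges as d -> -(3/4) ln(1 - 4p/3), so cap targets below that.
_MAX_DIVERGENCE = 0.74


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters controlling one synthetic dataset.

    ``demog`` is ``(n1_ratio, n2_ratio, t_gens)``: ancestral and current
    population sizes as multiples of the simulation grid size
    (``grid_two_n`` chromosomes at ratio 1) and the number of generations
    since the step change.  ``dfe_mean_S`` is the mean of ``N_e s`` over
    new deleterious amino acid mutations, expressed on the weighted recent
    population size implied by ``demog``.
    """

    n_loci: int = 77
    exon_len: int = 498
    intron_len: int = 600
    n_individuals: int = 15
    missing_rate: float = 0.0
    theta_neutral: float = 0.008
    dfe_shape: float = 0.3
    dfe_mean_S: float = 1000.0
    demog: Tuple[float, float, int] = (1.0, 2.0, 100)
    alpha_true: float = 0.0
    div_neutral_close: float = 0.03
    div_neutral_far: float = 0.19
    inbreeding_F: float = 0.0
    seed: int = 0
    # implementation knobs (not biological parameters)
    grid_two_n: int = 100
    n_s_bins: int = 24

    def __post_init__(self) -> None:
        probs = {
            "missing_rate": self.missing_rate,
            "inbreeding_F": self.inbreeding_F,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.alpha_true < 1.0:
            raise ValueError(f"alpha_true must be in [0, 1), got {self.alpha_true}")
        if self.dfe_shape <= 0:
            raise ValueError("dfe_shape must be > 0")
        if self.dfe_mean_S < 0:
            raise ValueError("dfe_mean_S must be >= 0")
        if self.theta_neutral < 0:
            raise ValueError("theta_neutral must be >= 0")
        for name in ("div_neutral_close", "div_neutral_far"):
            d = getattr(self, name)
            if not 0.0 <= d < _MAX_DIVERGENCE:
                raise ValueError(f"{name} must be in [0, {_MAX_DIVERGENCE}), got {d}")
        if self.exon_len % 3 != 0:
            raise ValueError(f"exon_len must be a multiple of 3, got {self.exon_len}")
        if self.exon_len <= 0 or self.intron_len < 0:
            raise ValueError("locus lengths must be positive")
        if self.n_loci < 1 or self.n_individuals < 1:
            raise ValueError("n_loci and n_individuals must be >= 1")
        n1, n2, t = self.demog
        if n1 <= 0 or n2 <= 0 or t < 0:
            raise ValueError(f"invalid demog {self.demog}")
        if self.grid_two_n < 4 or self.grid_two_n % 2 != 0:
            raise ValueError("grid_two_n must be an even integer >= 4")

    # -- demography on the simulation grid ---------------------------------

    @property
    def two_n1(self) -> int:
        return int(round(self.grid_two_n * self.demog[0]))

    @property
    def two_n2(self) -> int:
        return int(round(self.grid_two_n * self.demog[1]))

    @property
    def t_gens(self) -> int:
        return int(self.demog[2])

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_individuals

    def weighted_n(self) -> float:
        """Weighted recent diploid population size of the simulated demography."""
        import math

        n1 = self.two_n1 / 2.0
        n2 = self.two_n2 / 2.0
        t = self.t_gens
        if t == 0:
            return n1
        f2 = 1.0 - math.exp(-t / (2.0 * n2))
        return n1 * (1.0 - f2) + n2 * f2

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demog"] = list(self.demog)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "demog" in d:
            d["demog"] = tuple(d["demog"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kwargs) -> "SimulationConfig":
        d = self.to_dict()
        d.update(kwargs)
        return SimulationConfig.from_dict(d)
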
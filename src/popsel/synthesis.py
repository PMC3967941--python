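"""Synthetic study inputs: control panels, HKA counts, case/control tables.

Everything the pipeline consumes can be generated here without downloads:
multi-population panels of unlinked neutral loci (the "control gene" set
used to build empirical nulls), polymorphism/divergence counts for the HKA
test, selective-sweep loci from the forward simulator, and case/control
genotype counts drawn from the penetrance model.  All generators are
seed-deterministic and echo their seed in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import GenotypeCounts, model_probabilities
from .coalescent import DemographyConfig, PopulationConfig, simulate_coalescent_locus
from .haplotypes import HaplotypeMatrix


@dataclass
class PanelConfig:
    """Control-panel generation settings.

    The default emulates the reference design: ~1,000 unlinked gene-sized
    loci sampled in an African-like constant-size population and a
    non-African-like population with an out-of-Africa bottleneck, with
    per-locus theta drawn from a log-normal (median 5 per locus, i.e. about
    1e-3 per bp over a 5 kb gene).
    """

    n_loci: int = 987
    samples: dict[str, int] = field(default_factory=lambda: {"AFR": 40, "EUR": 40})
    L: int = 5_000
    theta_log_mean: float = float(np.log(5.0))
    theta_log_sd: float = 0.5
    demography: DemographyConfig | None = None
    seed: int = 0

    def resolved_demography(self) -> DemographyConfig:
        if self.demography is not None:
            return self.demography
        pops = []
        for name in self.samples:
            if name == "AFR":
                pops.append(PopulationConfig(name))
            else:
                # out-of-Africa-like bottleneck then recovery
                pops.append(PopulationConfig(
                    name, epochs=[(0.0, 1.0), (0.02, 0.15), (0.08, 1.0)]))
        names = list(self.samples)
        splits = [(0.08, n, names[0]) for n in names[1:]]
        return DemographyConfig(populations=pops, splits=splits)


def generate_control_panel(
    cfg: PanelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[HaplotypeMatrix]:
    """Independent neutral loci under a shared demography; seed-deterministic."""
    cfg = cfg or PanelConfig()
    if cfg.n_loci < 1:
        raise ValueError("need at least one locus")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    demog = cfg.resolved_demography()
    panel = []
    for i in range(cfg.n_loci):
        theta = float(rng.lognormal(cfg.theta_log_mean, cfg.theta_log_sd))
        hap = simulate_coalescent_locus(
            dict(cfg.samples), theta, demog, L=cfg.L, rng=rng,
            region_id=f"control{i}")
        hap.seed = cfg.seed  # type: ignore[attr-defined]
        panel.append(hap)
    return panel


def simulate_case_control_counts(
    q: float, beta: float, gamma: float, kp: float,
    n_cases: int, n_controls: int,
    rng: np.random.Generator | None = None, seed: int | None = None,
) -> tuple[GenotypeCounts, GenotypeCounts]:
    """Multinomial case/control genotype counts under the penetrance model."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    probs = model_probabilities(q, beta, gamma, kp)
    if probs is None:
        raise ValueError("parameters give an infeasible alpha (penetrance outside (0,1))")
    case_p, ctrl_p, _ = probs
    c = rng.multinomial(n_cases, case_p)
    k = rng.multinomial(n_controls, ctrl_p)
    return (GenotypeCounts("cases", *map(int, c)),
            GenotypeCounts("controls", *map(int, k)))
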
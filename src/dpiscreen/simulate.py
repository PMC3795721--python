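"""Synthetic plate readouts with known binding ground truth.

The generator emulates probing a designed plate with a DNA-binding
protein: a binder model assigns every dsDNA motif class an affinity
(full signal for consensus matches, multiplicatively penalized per
mismatch, both strands always considered), each well's signal is the
background plus the best window of its probe, positive-control wells get
a fixed full-scale signal, and plate noise is added on top. Every run is
reproducible from its seed.

Defaults are the package's reference study conditions: background 0.1
absorbance units, signal gain 1.0 (ten-fold over background), mismatch
penalty 0.2 and Gaussian noise with sd 0.05 (half the background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    canonical_representative,
    forward_windows,
    iupac_match,
    reverse_complement,
)
from .plate import PlateLayout, PlateReadout, ProbeRecord, all_wells

__all__ = ["BinderModel", "NoiseModel", "probe_signal", "simulate_readout"]


def _min_mismatches(kmer: str, consensus: str) -> int:
    """Best (fewest-mismatch) sliding alignment of a degenerate consensus
    against a k-mer or its reverse complement."""
    best = len(kmer)
    for seq in (kmer, reverse_complement(kmer)):
        if len(consensus) <= len(seq):
            for off in range(len(seq) - len(consensus) + 1):
                mm = sum(
                    not iupac_match(sym, b)
                    for sym, b in zip(consensus, seq[off : off + len(consensus)])
                )
                best = min(best, mm)
        else:
            for off in range(len(consensus) - len(seq) + 1):
                mm = sum(
                    not iupac_match(sym, b)
                    for sym, b in zip(consensus[off : off + len(seq)], seq)
                )
                best = min(best, mm)
    return best


@dataclass
class BinderModel:
    """Hexamer-affinity model of one DNA-binding protein.

    ``affinity(m) = scale * penalty**mismatches(m, consensus)`` unless an
    explicit per-motif affinity overrides it; ``explicit_affinities``
    alone (consensus None) models a binder of exactly those motifs.
    ``combine="max"`` treats a probe's wells as monomeric single-site
    binding (best window wins); ``"sum"`` adds windows up.
    """

    consensus: str | None = None
    per_mismatch_penalty: float = 0.2
    explicit_affinities: dict[str, float] = field(default_factory=dict)
    background: float = 0.1
    scale: float = 1.0
    combine: str = "max"
    positive_control_signal: float | None = None  # defaults to scale

    def __post_init__(self) -> None:
        if not 0 < self.per_mismatch_penalty <= 1:
            raise ValueError("per-mismatch penalty must be in (0, 1]")
        if self.consensus is None and not self.explicit_affinities:
            raise ValueError("need a consensus or explicit affinities")
        if self.combine not in ("max", "sum"):
            raise ValueError("combine must be 'max' or 'sum'")
        self.explicit_affinities = {
            canonical_representative(m): a
            for m, a in self.explicit_affinities.items()
        }
        self._cache: dict[str, float] = {}

    def affinity(self, motif: str) -> float:
        """Affinity of one canonical motif class (arbitrary units >= 0)."""
        rep = canonical_representative(motif)
        if rep in self.explicit_affinities:
            return self.explicit_affinities[rep]
        if self.consensus is None:
            return 0.0
        if rep not in self._cache:
            mm = _min_mismatches(rep, self.consensus)
            self._cache[rep] = self.scale * self.per_mismatch_penalty**mm
        return self._cache[rep]


def probe_signal(probe: ProbeRecord | None, binder: BinderModel, k: int = 6) -> float:
    """Noise-free expected absorbance of one well.

    Empty wells and negative controls sit at background; positive
    controls always bind at full scale; library probes add the binder's
    best (or summed) window affinity over both strands of the variable
    region.
    """
    if probe is None or probe.probe_class == "empty":
        return binder.background
    if probe.probe_class == "positive_control":
        sig = (
            binder.positive_control_signal
            if binder.positive_control_signal is not None
            else binder.scale
        )
        return binder.background + sig
    if probe.probe_class == "negative_control":
        return binder.background
    if len(probe.variable_region) < k:
        return binder.background
    affinities = [
        binder.affinity(w) for w in forward_windows(probe.variable_region, k)
    ]
    total = max(affinities) if binder.combine == "max" else sum(affinities)
    return binder.background + total


@dataclass
class NoiseModel:
    """Additive plate noise; Gaussian by default, optionally lognormal."""

    distribution: str = "gaussian"
    sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError("distribution must be 'gaussian' or 'lognormal'")

    def draw(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.sd == 0:
            return np.zeros(n)
        if self.distribution == "gaussian":
            return rng.normal(0.0, self.sd, n)
        # lognormal centered so the median perturbation is zero
        return rng.lognormal(0.0, self.sd, n) - 1.0


def simulate_readout(
    layout: PlateLayout,
    binder: BinderModel,
    noise: NoiseModel | None = None,
    k: int = 6,
    extract_id: str = "simulated",
) -> PlateReadout:
    """One simulated 384-well readout: signal plus noise, clipped at zero."""
    noise = noise or NoiseModel(sd=0.0)
    wells = all_wells()
    signal = np.array(
        [probe_signal(layout.probe_at(w), binder, k) for w in wells]
    )
    values = np.clip(signal + noise.draw(len(wells)), 0.0, None)
    return PlateReadout(
        values=dict(zip(wells, values.tolist())), extract_id=extract_id
    )
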
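"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here: flow-through
peptide log-ratios under the null, glycopeptide quantification tables with
spiked fold changes, persistent-random-walk nucleus tracks, and correlated
two-channel image pairs.  Each generator takes an explicit seed (or rng) and
is bit-reproducible; ground truth is returned in a separate table, never
embedded in the simulated records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "GlycoSimConfig",
    "TrackSimConfig",
    "default_sites_per_protein_dist",
    "simulate_flowthrough_ratios",
    "simulate_glyco_dataset",
    "simulate_tracks",
    "simulate_image_pair",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRVW"))  # no S/T/Y: sites placed explicitly

#: Null scale whose 3-sigma interval is +/-0.55 on log10, the flow-through
#: calibration of the dimethyl M/L doublet quantification.
NULL_SIGMA_DEFAULT = 0.55 / 3.0

#: Residue draw for O-glycosites: threonine 78.5%, serine 21.2%, tyrosine 0.3%.
RESIDUE_PROBS = {"T": 0.785, "S": 0.212, "Y": 0.003}


def default_sites_per_protein_dist(max_sites: int = 27) -> dict[int, float]:
    """Distribution of glycosites per protein emulating the embryo
    O-glycoproteome: 44% single-site, 20% two-site, geometric tail up to
    ``max_sites`` tuned so the mean is ~3.5 sites/protein (936 sites over
    270 proteins)."""
    dist = {1: 0.44, 2: 0.20}
    q = 0.811  # geometric decay of the tail; conditional tail mean ~7.3
    tail_mass = 1.0 - sum(dist.values())
    ks = np.arange(3, max_sites + 1)
    w = q ** (ks - 3)
    w = w / w.sum() * tail_mass
    for k, p in zip(ks, w):
        dist[int(k)] = float(p)
    return dist


def _validate_dist(dist: Mapping[int, float], name: str) -> None:
    if not dist:
        raise ValueError(f"{name} must be non-empty")
    if any((not isinstance(k, (int, np.integer))) or k < 1 for k in dist):
        raise ValueError(f"{name} keys must be positive integers")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} probabilities must be non-negative")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must sum to 1")


@dataclass(frozen=True)
class GlycoSimConfig:
    """Configuration for the synthetic glycopeptide quantification table.

    Defaults emulate the wild-type embryo T/Tn O-glycoproteome: 270
    glycoproteins, ~3.5 sites per protein with 44% single-site, site
    glycoform classes 74% Tn-only / 4% T-only / 22% both, a zero-centred
    normal null on log10(mutant/control) whose 3-sigma half-width is 0.55,
    10% of sites carrying a true effect drawn from {-log10 50, -1, +1},
    and 30% of spectra lacking the isotope partner (singletons).
    """

    n_proteins: int = 270
    sites_per_protein_dist: Mapping[int, float] = field(
        default_factory=default_sites_per_protein_dist
    )
    tn_only_prob: float = 0.74
    t_only_prob: float = 0.04
    both_prob: float = 0.22
    null_sigma: float = NULL_SIGMA_DEFAULT
    frac_changed: float = 0.10
    effect_log10: Sequence[float] = (-math.log10(50.0), -1.0, 1.0)
    psm_per_site_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    singleton_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        probs = (self.tn_only_prob, self.t_only_prob, self.both_prob)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("glycoform class probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("glycoform class probabilities must sum to 1")
        if self.null_sigma <= 0:
            raise ValueError("null_sigma must be > 0")
        if not 0.0 <= self.frac_changed <= 1.0:
            raise ValueError("frac_changed must lie in [0, 1]")
        if not 0.0 <= self.singleton_rate <= 1.0:
            raise ValueError("singleton_rate must lie in [0, 1]")
        if self.frac_changed > 0 and len(self.effect_log10) == 0:
            raise ValueError("effect_log10 must be non-empty when frac_changed > 0")
        _validate_dist(self.sites_per_protein_dist, "sites_per_protein_dist")
        _validate_dist(self.psm_per_site_dist, "psm_per_site_dist")


@dataclass(frozen=True)
class TrackSimConfig:
    """Persistent-random-walk track generator settings.

    dt defaults to the 40 s two-photon frame rate; speed to the 2.46 um/min
    control macrophage head-migration mean.  persistence in [0, 1) blends
    the previous heading with a fresh isotropic direction; 0 is an
    uncorrelated random walk, values near 1 approach straight motion.
    """

    n_tracks: int = 50
    n_frames: int = 60
    dt: float = 40.0
    speed: float = 2.46
    persistence: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")


def simulate_flowthrough_ratios(
    n: int, sigma: float = NULL_SIGMA_DEFAULT, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` null log10 M/L ratios for flow-through (non-glycosylated)
    peptides: N(0, sigma), the empirical null used to calibrate the
    candidate cutoff."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sigma, size=int(n))


def _random_peptide(rng: np.random.Generator, residue: str) -> str:
    length = int(rng.integers(8, 16))
    aas = rng.choice(_AMINO_ACIDS, size=length)
    pos = int(rng.integers(0, length))
    aas[pos] = residue
    return "".join(aas) + "K"  # tryptic-looking C-terminus


def simulate_glyco_dataset(
    config: GlycoSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PSM-level glycopeptide quantification table plus its
    ground truth.

    Returns ``(records, truth)``.  ``records`` has one row per PSM with
    columns protein_id, peptide, site_position, residue, glycoform (Tn/T),
    intensity_medium (control channel), intensity_light (mutant channel;
    NaN for singletons), paired.  ``truth`` has one row per glycosite with
    the true glycoform class and true log10 effect (0 for unchanged sites).
    The log10 ratio of every paired PSM equals the site's true effect plus
    null noise.
    """
    rng = np.random.default_rng(config.seed)

    site_ks = np.array(sorted(config.sites_per_protein_dist))
    site_ps = np.array([config.sites_per_protein_dist[k] for k in site_ks], float)
    site_ps = site_ps / site_ps.sum()
    psm_ks = np.array(sorted(config.psm_per_site_dist))
    psm_ps = np.array([config.psm_per_site_dist[k] for k in psm_ks], float)
    psm_ps = psm_ps / psm_ps.sum()
    class_names = np.array(["Tn-only", "T-only", "both"])
    class_ps = np.array([config.tn_only_prob, config.t_only_prob, config.both_prob])
    residues = np.array(list(RESIDUE_PROBS))
    residue_ps = np.array(list(RESIDUE_PROBS.values()))
    effects = np.asarray(config.effect_log10, float)

    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(config.n_proteins):
        protein_id = f"SYNP{i + 1:04d}"
        n_sites = int(rng.choice(site_ks, p=site_ps))
        positions = np.sort(rng.choice(np.arange(1, 1001), size=n_sites, replace=False))
        for pos in positions:
            residue = str(rng.choice(residues, p=residue_ps))
            site_class = str(rng.choice(class_names, p=class_ps))
            changed = rng.random() < config.frac_changed
            effect = float(rng.choice(effects)) if changed else 0.0
            truth_rows.append(
                {
                    "protein_id": protein_id,
                    "site_position": int(pos),
                    "residue": residue,
                    "glycoform_class": site_class,
                    "effect_log10": effect,
                }
            )
            glycoforms = {"Tn-only": ["Tn"], "T-only": ["T"], "both": ["Tn", "T"]}[
                site_class
            ]
            peptide = _random_peptide(rng, residue)
            for gf in glycoforms:
                n_psm = int(rng.choice(psm_ks, p=psm_ps))
                for _ in range(n_psm):
                    medium = 10.0 ** rng.normal(6.0, 0.5)
                    log_ratio = effect + rng.normal(0.0, config.null_sigma)
                    singleton = rng.random() < config.singleton_rate
                    rec_rows.append(
                        {
                            "protein_id": protein_id,
                            "peptide": peptide,
                            "site_position": int(pos),
                            "residue": residue,
                            "glycoform": gf,
                            "intensity_medium": medium,
                            "intensity_light": (
                                np.nan if singleton else medium * 10.0**log_ratio
                            ),
                            "paired": not singleton,
                        }
                    )
    records = pd.DataFrame(rec_rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_tracks(config: TrackSimConfig) -> list[Track]:
    """Simulate 3D nucleus tracks as fixed-step persistent random walks.

    Every step has length speed*dt (speed converted to um/s); the heading
    is a unit blend ``normalize(p * previous + (1 - p) * fresh)`` with
    ``p = persistence`` and ``fresh`` uniform on the sphere, so p -> 1
    gives straight lines and p = 0 an isotropic random walk.
    """
    rng = np.random.default_rng(config.seed)
    step_len = config.speed / 60.0 * config.dt  # um per frame
    times = np.arange(config.n_frames, dtype=float) * config.dt
    tracks: list[Track] = []
    for tid in range(config.n_tracks):
        headings = np.empty((config.n_frames - 1, 3))
        d = _random_unit(rng)
        for j in range(config.n_frames - 1):
            if j > 0:
                blend = config.persistence * d + (1 - config.persistence) * _random_unit(rng)
                norm = np.linalg.norm(blend)
                # degenerate cancellation: keep previous heading
                d = blend / norm if norm > 1e-12 else d
            headings[j] = d
        start = rng.uniform(0.0, 100.0, size=3)
        positions = np.vstack([start, start + np.cumsum(step_len * headings, axis=0)])
        tracks.append(
            Track(track_id=f"SIM{tid + 1:04d}", times=times.copy(), positions=positions)
        )
    return tracks


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def simulate_image_pair(
    height: int, width: int, rho: float, seed: int = 0
):
    """Generate a two-channel image pair whose pixel intensities have
    Pearson correlation converging to ``rho`` as the pixel count grows.

    Channels are affine-rescaled Gaussian fields (channel_b = rho * z_a +
    sqrt(1 - rho^2) * z_ind), shifted to positive intensities; the Pearson
    coefficient is invariant to that rescaling.
    """
    from .imaging import ImagePair  # local import to avoid a cycle

    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z_a = rng.normal(size=(height, width))
    z_b = rho * z_a + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(
        size=(height, width)
    )
    channel_a = 100.0 + 20.0 * z_a
    channel_b = 150.0 + 30.0 * z_b
    return ImagePair(channel_a=channel_a, channel_b=channel_b)
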
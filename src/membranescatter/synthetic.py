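"""Seeded ground-truth generators for every pipeline stage.

Each generator evaluates the corresponding forward model at known
parameters, adds a stated noise model and returns the dataset together
with a :class:`GroundTruthBundle` recording the generating parameters,
the seed and the noise model — the only authoritative source of truth
for recovery studies.  Regenerating with the same seed reproduces a
dataset bit-identically.

Default noise levels are 2% (fraction of the peak signal, Gaussian) for
CD spectra, WAXS angular profiles and form-factor magnitudes, and
Poisson-like counting noise for diffuse maps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .cd import BasisSet, MRESpectrum
from .laxs import DiffuseMap, StackParameters, StructureFactorEngine, model_intensity
from .sdp import FormFactorData, SDPModel
from .waxs import AngularProfile, angular_intensity_model

__all__ = [
    "GroundTruthBundle",
    "gen_cd_spectrum",
    "gen_waxs_profile",
    "gen_form_factor",
    "gen_diffuse_map",
]


@dataclass(frozen=True)
class GroundTruthBundle:
    """Provenance record written next to every synthetic dataset."""

    generator: str
    seed: int
    noise_model: str
    params: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            return v
        return json.dumps(clean(asdict(self)), indent=2)


def gen_cd_spectrum(
    fractions,
    basis: BasisSet,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_residues: int = 16,
) -> tuple[MRESpectrum, GroundTruthBundle]:
    """MRE spectrum = basis @ fractions + Gaussian noise.

    ``fractions`` must lie on the probability simplex; ``noise_sd`` is
    the noise standard deviation as a fraction of max |signal|.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size != 4 or np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 4 nonnegative values summing to 1")
    signal = basis.spectra @ f
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * np.max(np.abs(signal)), signal.shape) \
        if noise_sd > 0 else 0.0
    spec = MRESpectrum(basis.wavelength_nm, signal + noise, n_residues=n_residues)
    bundle = GroundTruthBundle(
        "gen_cd_spectrum", seed, "gaussian fraction-of-signal",
        {"fractions": f, "noise_sd": noise_sd, "n_residues": n_residues},
    )
    return spec, bundle


def gen_waxs_profile(
    m: float,
    scale: float = 100.0,
    baseline: float = 5.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    phi_deg: np.ndarray | None = None,
) -> tuple[AngularProfile, GroundTruthBundle]:
    """I(phi) = scale * MaierSaupe(m) + baseline + Gaussian noise."""
    if phi_deg is None:
        phi_deg = np.linspace(0.0, 85.0, 70)
    phi_deg = np.asarray(phi_deg, dtype=float)
    signal = angular_intensity_model(m, phi_deg, scale=scale, baseline=baseline)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * np.max(np.abs(signal)), signal.shape) \
        if noise_sd > 0 else 0.0
    prof = AngularProfile(phi_deg, signal + noise)
    bundle = GroundTruthBundle(
        "gen_waxs_profile", seed, "gaussian fraction-of-signal",
        {"m": m, "scale": scale, "baseline": baseline, "noise_sd": noise_sd},
    )
    return prof, bundle


def gen_form_factor(
    model: SDPModel,
    q_z: np.ndarray,
    noise_sd: float = 0.02,
    seed: int = 0,
    hidden_scale: float | None = None,
) -> tuple[FormFactorData, GroundTruthBundle]:
    """|F(q_z)| times a hidden per-sample scale plus Gaussian noise.

    The hidden scale (drawn log-uniform in [0.5, 2] unless given)
    emulates the arbitrary normalization of experimental form factors;
    it is recorded in the bundle.
    """
    rng = np.random.default_rng(seed)
    if hidden_scale is None:
        hidden_scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    q_z = np.asarray(q_z, dtype=float)
    f = model.form_factor(q_z) * hidden_scale
    sd = noise_sd * f.max()
    noisy = f + (rng.normal(0.0, sd, f.shape) if noise_sd > 0 else 0.0)
    noisy = np.abs(noisy)  # magnitudes are reported as nonnegative
    sigma = np.full_like(f, max(sd, 1e-12))
    data = FormFactorData(q_z, noisy, sigma)
    bundle = GroundTruthBundle(
        "gen_form_factor", seed, "gaussian fraction-of-signal",
        {
            "noise_sd": noise_sd, "hidden_scale": hidden_scale,
            "a_l": model.params.a_l, "params": asdict(model.params),
            "peptide": asdict(model.peptide) if model.peptide else None,
            "composition": model.composition.name,
        },
    )
    return data, bundle


def gen_diffuse_map(
    p: StackParameters,
    form_factor: np.ndarray,
    q_r: np.ndarray,
    q_z: np.ndarray,
    noise_level: float = 0.05,
    seed: int = 0,
    q_nodes=None,
) -> tuple[DiffuseMap, GroundTruthBundle]:
    """Forward-modelled diffuse map with Poisson-like counting noise.

    The noiseless map is scaled so its brightest pixel carries
    ``1/noise_level**2`` counts (5% relative noise at the peak by
    default) and each pixel receives Gaussian noise of variance equal to
    its count — the large-count limit of Poisson statistics.  Noise is
    applied to the symmetrized (q_r >= 0) representation, so the
    implicit I(q_r) = I(-q_r) symmetry is preserved.
    """
    engine = StructureFactorEngine(p, np.asarray(q_r, float), np.asarray(q_z, float),
                                   q_nodes=q_nodes)
    s = engine.structure_factor(p.kc, p.b)
    clean = model_intensity(s, engine.q_r, engine.q_z, np.asarray(form_factor, float))
    if noise_level > 0:
        peak = 1.0 / noise_level**2
        clean = clean * (peak / clean.max())
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * np.sqrt(np.clip(clean, 0.0, None))
    else:
        noisy = clean
    data = DiffuseMap(engine.q_r, engine.q_z, noisy)
    bundle = GroundTruthBundle(
        "gen_diffuse_map", seed, "poisson-like counts",
        {
            "kc": p.kc, "b": p.b, "n_layers": p.n_layers,
            "domain_lr": p.domain_lr, "d_spacing": p.d_spacing,
            "temperature": p.temperature, "noise_level": noise_level,
        },
    )
    return data, bundle
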
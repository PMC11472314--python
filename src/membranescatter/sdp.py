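"""Scattering-density-profile (SDP) modelling of bilayer form factors.

The bilayer is described by volume-occupancy profiles of component
groups along the normal ``z`` (origin at the bilayer midplane,
symmetric): Phos (phosphate plus outer headgroup) and CG
(carbonyl/glycerol) as symmetric Gaussian pairs, the hydrocarbon region
as a plateau bounded by error-function edges from which the terminal
CH3 Gaussian (and any peptide density placed inside the core) is
carved out, and Water filling whatever volume remains so the occupancies
sum to one everywhere.  A peptide is an additional Gaussian envelope
whose placement — headgroup, hydrocarbon, or both — is a model
hypothesis ranked by chi-square after fitting.

Each group occupies volume ``V`` and carries ``e`` electrons, giving the
electron density rho(z) = sum_i (e_i / V_i) P_i(z); the measurable form
factor is the cosine transform of the contrast against water,

    F(q_z) = int (rho(z) - rho_w) cos(q_z z) dz.

Derived structural quantities follow the standard conventions: ``D_HH``
is the peak-to-peak distance of the combined Phos+CG electron density,
``2D_C`` the full width at half maximum of the hydrocarbon occupancy,
and ``A_L`` the area per lipid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import simpson
from scipy.optimize import least_squares
from scipy.special import erf
from sklearn.base import BaseEstimator

__all__ = [
    "GroupSpec",
    "LipidComposition",
    "PeptideEnvelope",
    "SDPParams",
    "SDPModel",
    "FormFactorData",
    "StructuralSummary",
    "load_compositions",
    "default_composition",
    "build_sdp_model",
    "electron_density",
    "form_factor",
    "FormFactorFitter",
    "fit_form_factor",
    "select_peptide_location",
    "derive_structure",
]

_DATA_DIR = Path(__file__).parent / "data"

HYPOTHESES = ("none", "headgroup", "hydrocarbon", "both")


@dataclass(frozen=True)
class GroupSpec:
    """Molecular volume (A^3) and electron count of a component group."""

    volume: float
    electrons: float

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("group volume must be positive")
        if self.electrons < 0:
            raise ValueError("electron count must be nonnegative")

    @property
    def density(self) -> float:
        return self.electrons / self.volume


@dataclass(frozen=True)
class LipidComposition:
    """Effective one-lipid component volumes/electrons for a mixture.

    Lipid mixtures are collapsed to a single effective lipid with
    composition-weighted volumes and electron counts, since one electron
    density profile is fitted per mixture.
    """

    name: str
    phos: GroupSpec
    cg: GroupSpec
    ch2: GroupSpec
    ch3: GroupSpec
    water: GroupSpec = GroupSpec(30.0, 10.0)

    @property
    def rho_water(self) -> float:
        return self.water.density


@dataclass(frozen=True)
class PeptideEnvelope:
    """Peptide Gaussian envelope specification.

    volume/electrons are per peptide molecule; ``lipid_per_peptide`` is
    the lipid:peptide molar ratio.  ``center``/``width`` place the
    (symmetric pair of) Gaussians; for the "both" hypothesis a second
    envelope is given and ``split`` is the volume fraction assigned to
    the first (headgroup) one.
    """

    volume: float
    electrons: float
    lipid_per_peptide: float
    center: float
    width: float
    center2: float | None = None
    width2: float | None = None
    split: float = 1.0

    def __post_init__(self):
        if self.volume <= 0 or self.lipid_per_peptide <= 0:
            raise ValueError("peptide volume and molar ratio must be positive")
        if not 0.0 <= self.split <= 1.0:
            raise ValueError("split must lie in [0, 1]")


@dataclass(frozen=True)
class SDPParams:
    """Free structural parameters of the symmetric bilayer model."""

    a_l: float  # area per lipid, A^2
    z_phos: float = 22.0
    sigma_phos: float = 2.8
    z_cg: float = 17.5
    sigma_cg: float = 2.5
    sigma_ch3: float = 2.9
    sigma_edge: float = 2.5

    def __post_init__(self):
        if self.a_l <= 0:
            raise ValueError("area per lipid must be positive")
        for w in (self.sigma_phos, self.sigma_cg, self.sigma_ch3, self.sigma_edge):
            if w <= 0:
                raise ValueError("profile widths must be positive")


def load_compositions(path: str | Path | None = None) -> dict[str, LipidComposition]:
    """Load lipid component tables from YAML (default: packaged file)."""
    path = Path(path) if path is not None else _DATA_DIR / "lipid_components.yaml"
    raw = yaml.safe_load(path.read_text())
    out = {}
    for name, groups in raw.items():
        kwargs = {g: GroupSpec(float(v["volume"]), float(v["electrons"]))
                  for g, v in groups.items()}
        out[name] = LipidComposition(name=name, **kwargs)
    return out


def default_composition(name: str = "gneg_im") -> LipidComposition:
    return load_compositions()[name]


def _gauss_pair(z, center, width):
    """Unit-area Gaussian mirrored about z = 0 (sum of both copies)."""
    norm = 1.0 / (width * np.sqrt(2.0 * np.pi))
    return norm * (np.exp(-0.5 * ((z - center) / width) ** 2)
                   + np.exp(-0.5 * ((z + center) / width) ** 2))


def _plateau(z, half_width, edge):
    """Unit-height plateau on |z| < half_width with erf edges."""
    s = edge * np.sqrt(2.0)
    return 0.5 * (erf((half_width - z) / s) + erf((half_width + z) / s))


_TRANSFORM_CACHE: dict[tuple, np.ndarray] = {}


def _transform_matrix(q_z: np.ndarray, zh: np.ndarray) -> np.ndarray:
    """Cosine-transform matrix with Simpson weights folded in.

    ``M @ contrast`` integrates contrast * cos(q z) over the half grid;
    cached because fits evaluate thousands of models on the same grids.
    """
    key = (q_z.tobytes(), zh.size, float(zh[0]), float(zh[-1]))
    mat = _TRANSFORM_CACHE.get(key)
    if mat is None:
        if len(_TRANSFORM_CACHE) > 16:
            _TRANSFORM_CACHE.clear()
        dz = zh[1] - zh[0]
        w = np.ones(zh.size)
        if zh.size % 2 == 1:  # composite Simpson on the uniform grid
            w[1:-1:2], w[2:-1:2] = 4.0, 2.0
            w *= dz / 3.0
        else:  # fall back to trapezoid for even-sized grids
            w *= dz
            w[[0, -1]] = dz / 2.0
        mat = np.cos(np.outer(q_z, zh)) * w[None, :]
        _TRANSFORM_CACHE[key] = mat
    return mat


class SDPModel:
    """A constructed (or fitted) scattering-density-profile model.

    Attributes
    ----------
    z : ndarray
        Symmetric z grid (A).
    occupancy : dict[str, ndarray]
        Volume-occupancy profiles for phos, cg, ch2, ch3, peptide
        (all-zero when absent) and water; they sum to one at every z.
    d_c : float
        Hydrocarbon half-thickness solved from volume conservation.
    overfill : float
        Integrated occupancy excess (A of excess probability); zero for
        a feasible model.  With ``strict=True`` (the default) any excess
        beyond numerical tolerance raises instead.
    """

    def __init__(
        self,
        composition: LipidComposition,
        params: SDPParams,
        peptide: PeptideEnvelope | None = None,
        z_max: float = 45.0,
        dz: float = 0.025,
        strict: bool = True,
    ):
        self.composition = composition
        self.params = params
        self.peptide = peptide
        n_half = int(round(z_max / dz))
        self.z = np.linspace(-z_max, z_max, 2 * n_half + 1)
        z = self.z
        a_l = params.a_l
        c = composition

        p_phos = (c.phos.volume / a_l) * _gauss_pair(z, params.z_phos, params.sigma_phos)
        p_cg = (c.cg.volume / a_l) * _gauss_pair(z, params.z_cg, params.sigma_cg)
        p_ch3 = (c.ch3.volume / a_l) * _gauss_pair(z, 0.0, params.sigma_ch3)

        if peptide is not None:
            v_patch = 2.0 * peptide.volume / (peptide.lipid_per_peptide * a_l)
            p_pep = peptide.split * v_patch * _gauss_pair(z, peptide.center, peptide.width)
            if peptide.center2 is not None:
                p_pep = p_pep + (1.0 - peptide.split) * v_patch * _gauss_pair(
                    z, peptide.center2, peptide.width2)
        else:
            p_pep = np.zeros_like(z)

        # hydrocarbon half-thickness from volume conservation of CH2:
        # int (P_hc - P_ch3 - P_pep * P_hc) dz = 2 V_ch2 / A_L
        target = 2.0 * (c.ch2.volume + c.ch3.volume) / a_l
        d_c = target / 2.0
        if peptide is not None:
            for _ in range(12):
                p_hc = _plateau(z, d_c, params.sigma_edge)
                pep_inside = simpson(p_pep * p_hc, x=z)
                d_new = 0.5 * (target + pep_inside)
                if abs(d_new - d_c) < 1e-11:
                    d_c = d_new
                    break
                d_c = d_new
        p_hc = _plateau(z, d_c, params.sigma_edge)
        p_ch2 = p_hc - p_ch3 - p_pep * p_hc
        self.d_c = float(d_c)

        total = p_phos + p_cg + p_ch2 + p_ch3 + p_pep
        self.overfill = float(
            simpson(np.clip(total - 1.0, 0.0, None), x=z)
            + simpson(np.clip(-p_ch2, 0.0, None), x=z)
        )
        if strict:
            worst = int(np.argmax(total))
            if total[worst] > 1.0 + 1e-6:
                raise ValueError(
                    f"non-water occupancy exceeds 1 at z = {z[worst]:.2f} A "
                    f"(total {total[worst]:.4f}); model is overfilled"
                )
            if p_ch2.min() < -1e-6:
                zbad = z[int(np.argmin(p_ch2))]
                raise ValueError(f"CH2 occupancy negative at z = {zbad:.2f} A; "
                                 "peptide/CH3 overfill the hydrocarbon core")
        self.occupancy = {
            "phos": p_phos, "cg": p_cg, "ch2": p_ch2,
            "ch3": p_ch3, "peptide": p_pep, "water": 1.0 - total,
        }

    # -- derived profiles -------------------------------------------------

    def _group_density(self, name: str) -> float:
        c = self.composition
        if name == "peptide":
            return self.peptide.electrons / self.peptide.volume if self.peptide else 0.0
        return getattr(c, name).density

    def electron_density(self, z: np.ndarray | None = None):
        """Total and per-component electron density (e/A^3).

        Returns ``(rho_total, components)`` where components maps group
        name to its density contribution on the model grid.  Passing an
        explicit ``z`` interpolates the total onto it.
        """
        comps = {name: self._group_density(name) * occ if name != "water"
                 else self.composition.rho_water * occ
                 for name, occ in self.occupancy.items()}
        rho = sum(comps.values())
        if z is not None:
            return np.interp(np.asarray(z, float), self.z, rho)
        return rho, comps

    def form_factor(self, q_z: np.ndarray) -> np.ndarray:
        """|F(q_z)| from the contrast cosine transform (Simpson rule)."""
        return np.abs(self.signed_form_factor(q_z))

    def signed_form_factor(self, q_z: np.ndarray) -> np.ndarray:
        q_z = np.asarray(q_z, dtype=float)
        rho, _ = self.electron_density()
        contrast = rho - self.composition.rho_water
        half = self.z >= 0.0
        zh, ch = self.z[half], contrast[half]
        return 2.0 * (_transform_matrix(q_z, zh) @ ch)


def build_sdp_model(
    composition: LipidComposition,
    params: SDPParams,
    peptide: PeptideEnvelope | None = None,
    **kwargs,
) -> SDPModel:
    """Construct a volume-occupancy bilayer model (see :class:`SDPModel`)."""
    return SDPModel(composition, params, peptide, **kwargs)


def electron_density(model: SDPModel, z: np.ndarray | None = None):
    return model.electron_density(z)


def form_factor(model: SDPModel, q_z: np.ndarray) -> np.ndarray:
    return model.form_factor(q_z)


@dataclass(frozen=True)
class FormFactorData:
    """Measured |F(q_z)| on a relative scale, with optional uncertainties."""

    q_z: np.ndarray
    f: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        qz = np.asarray(self.q_z, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(qz) <= 0):
            raise ValueError("q_z grid must be strictly increasing")
        if f.shape != qz.shape:
            raise ValueError("|F| must match the q_z grid")
        if np.any(f < 0):
            raise ValueError("|F| must be nonnegative")
        object.__setattr__(self, "q_z", qz)
        object.__setattr__(self, "f", f)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != qz.shape or np.any(s <= 0):
                raise ValueError("sigma must be positive and match the grid")
            object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class StructuralSummary:
    """Headline structural quantities derived from a fitted model."""

    a_l: float
    d_hh: float
    two_d_c: float

    def __post_init__(self):
        if min(self.a_l, self.d_hh, self.two_d_c) <= 0:
            raise ValueError("structural quantities must be positive")


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic sub-grid refinement of a discrete maximum."""
    if i <= 0 or i >= x.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    return float(x[i] + 0.5 * (y[i - 1] - y[i + 1]) / denom * (x[1] - x[0]))


def derive_structure(model: SDPModel) -> StructuralSummary:
    """D_HH, 2D_C and A_L from a constructed or fitted model.

    D_HH is twice the position of the outer maximum of the combined
    Phos+CG electron density (parabolically refined); 2D_C is the FWHM
    of the total hydrocarbon (CH2+CH3) occupancy.
    """
    z = model.z
    _, comps = model.electron_density()
    head = comps["phos"] + comps["cg"]
    pos = z > 0
    zp, hp = z[pos], head[pos]
    i = int(np.argmax(hp))
    if hp[i] <= head[np.argmin(np.abs(z))] or zp[i] < 1.0:
        raise ValueError("headgroup density has no symmetric off-center maxima")
    d_hh = 2.0 * _refine_peak(zp, hp, i)

    hc = model.occupancy["ch2"] + model.occupancy["ch3"]
    peak = hc.max()
    above = hc >= 0.5 * peak
    idx = np.where(above)[0]
    j = idx[-1]
    # linear interpolation of the half-maximum crossing on the +z side
    if j < z.size - 1 and hc[j + 1] < hc[j]:
        frac = (hc[j] - 0.5 * peak) / (hc[j] - hc[j + 1])
        z_half = z[j] + frac * (z[j + 1] - z[j])
    else:
        z_half = z[j]
    two_d_c = 2.0 * float(z_half)
    return StructuralSummary(a_l=model.params.a_l, d_hh=d_hh, two_d_c=two_d_c)


class FormFactorFitter(BaseEstimator):
    """Bounded least-squares fit of an SDP model to |F(q_z)| data.

    The per-sample scale of the data (diffuse form factors are not on an
    absolute scale) is profiled out analytically.  The peptide-location
    hypothesis constrains the envelope center: within the hydrocarbon
    core (|z| < D_C), in the headgroup band (D_C < |z| < z_phos + 10 A),
    or one envelope in each with a fitted volume split.

    Parameters
    ----------
    template : tuple of (LipidComposition, SDPParams, PeptideEnvelope | None)
        Starting model; the peptide envelope supplies volume, electrons
        and molar ratio (its center/width are re-fitted).
    hypothesis : one of "none", "headgroup", "hydrocarbon", "both"

    Like other scattering-density-profile implementations, the fit
    applies soft Gaussian restraints pulling the component widths (and,
    weakly, the headgroup positions) toward the template values: |F| on
    a relative scale does not determine all profile widths
    independently, and without the restraints physically equivalent
    solutions trade area per lipid against edge widths.  Positions of
    the peptide envelope and the area per lipid are unrestrained.

    Attributes (after ``fit``): ``model_``, ``chi2_`` (reduced),
    ``scale_``, ``summary_``, ``converged_``.
    """

    def __init__(
        self,
        composition: LipidComposition,
        init_params: SDPParams,
        peptide: PeptideEnvelope | None = None,
        hypothesis: str = "none",
        a_l_bounds: tuple[float, float] = (50.0, 100.0),
        restraint_sd: dict[str, float] | None = None,
    ):
        self.composition = composition
        self.init_params = init_params
        self.peptide = peptide
        self.hypothesis = hypothesis
        self.a_l_bounds = a_l_bounds
        self.restraint_sd = restraint_sd

    #: default soft-restraint standard deviations (A); np.inf = unrestrained.
    #: widths are essentially fixed at their template values, positions are
    #: allowed to move when the data demand it
    _RESTRAINTS = {"a_l": 5.0, "z_phos": 0.3, "sigma_phos": 0.05, "z_cg": 0.3,
                   "sigma_cg": 0.05, "sigma_ch3": 0.05, "sigma_edge": 0.05,
                   "pep_width": 1.0}

    def _build(self, theta, strict: bool = False) -> SDPModel:
        p = SDPParams(a_l=theta[0], z_phos=theta[1], sigma_phos=theta[2],
                      z_cg=theta[3], sigma_cg=theta[4], sigma_ch3=theta[5],
                      sigma_edge=theta[6])
        pep = None
        if self.hypothesis == "headgroup" or self.hypothesis == "hydrocarbon":
            pep = replace(self.peptide, center=theta[7], width=theta[8],
                          center2=None, width2=None, split=1.0)
        elif self.hypothesis == "both":
            pep = replace(self.peptide, center=theta[7], width=theta[8],
                          center2=theta[9], width2=theta[10], split=theta[11])
        return SDPModel(self.composition, p, pep, strict=strict)

    def fit(self, data: FormFactorData):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.hypothesis != "none" and self.peptide is None:
            raise ValueError("peptide envelope required for a peptide hypothesis")
        ip = self.init_params
        base_model = SDPModel(self.composition, ip)
        d_c = base_model.d_c

        theta0 = [ip.a_l, ip.z_phos, ip.sigma_phos, ip.z_cg, ip.sigma_cg,
                  ip.sigma_ch3, ip.sigma_edge]
        lo = [self.a_l_bounds[0], ip.z_phos - 6, 1.0, ip.z_cg - 6, 1.0, 1.0, 1.0]
        hi = [self.a_l_bounds[1], ip.z_phos + 6, 6.0, ip.z_cg + 6, 6.0, 6.0, 6.0]
        if self.hypothesis == "headgroup":
            theta0 += [0.5 * (d_c + ip.z_phos), 3.0]
            lo += [d_c, 1.5]
            hi += [ip.z_phos + 10.0, 4.5]
        elif self.hypothesis == "hydrocarbon":
            theta0 += [0.5 * d_c, 3.0]
            lo += [0.0, 1.5]
            hi += [d_c, 4.5]
        elif self.hypothesis == "both":
            theta0 += [0.5 * (d_c + ip.z_phos), 3.0, 0.5 * d_c, 3.0, 0.5]
            lo += [d_c, 1.5, 0.0, 1.5, 0.0]
            hi += [ip.z_phos + 10.0, 4.5, d_c, 4.5, 1.0]
        if np.any(np.asarray(lo) > np.asarray(hi)):
            raise ValueError("infeasible hypothesis bounds for this template")

        w = 1.0 / data.sigma if data.sigma is not None else np.ones_like(data.f)
        # feasibility (occupancy <= 1 everywhere) enforced as a smooth penalty
        penalty_scale = 1e3 * float(np.median(w) * np.max(data.f))

        rsd = dict(self._RESTRAINTS)
        if self.restraint_sd:
            rsd.update(self.restraint_sd)
        prior_sd = [rsd["a_l"], rsd["z_phos"], rsd["sigma_phos"], rsd["z_cg"],
                    rsd["sigma_cg"], rsd["sigma_ch3"], rsd["sigma_edge"]]
        if self.hypothesis in ("headgroup", "hydrocarbon"):
            prior_sd += [np.inf, rsd["pep_width"]]
        elif self.hypothesis == "both":
            prior_sd += [np.inf, rsd["pep_width"], np.inf, rsd["pep_width"], np.inf]
        prior_sd = np.asarray(prior_sd)
        theta0_arr = np.asarray(theta0)

        def resid(theta):
            model = self._build(theta)
            fm = model.form_factor(data.q_z)
            denom = float((w * fm) @ (w * fm))
            scale = float((w * data.f) @ (w * fm)) / denom if denom > 0 else 0.0
            r = w * (data.f - scale * fm)
            restraints = (np.asarray(theta) - theta0_arr) / prior_sd
            restraints = restraints[np.isfinite(prior_sd)]
            return np.concatenate([r, restraints, [penalty_scale * model.overfill]])

        sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                            x_scale="jac", xtol=1e-12, ftol=1e-12)
        model = self._build(sol.x)
        fm = model.form_factor(data.q_z)
        scale = float((w * data.f) @ (w * fm)) / float((w * fm) @ (w * fm))
        dof = max(data.f.size - sol.x.size - 1, 1)
        self.model_ = model
        self.scale_ = scale
        self.chi2_ = float(np.sum((w * (data.f - scale * fm)) ** 2) / dof)
        self.feasible_ = model.overfill < 1e-3
        self.converged_ = bool(sol.status > 0)
        self.summary_ = derive_structure(model)
        return self

    def predict(self, q_z):
        return self.scale_ * self.model_.form_factor(np.asarray(q_z, float))


def fit_form_factor(
    data: FormFactorData,
    composition: LipidComposition,
    init_params: SDPParams,
    peptide: PeptideEnvelope | None = None,
    hypothesis: str = "none",
) -> FormFactorFitter:
    """Fit one peptide-location hypothesis; returns the fitted estimator."""
    est = FormFactorFitter(composition, init_params, peptide, hypothesis)
    return est.fit(data)


def select_peptide_location(
    fits: list[tuple[str, float]], ambiguity: float = 0.05
) -> tuple[str, bool]:
    """Pick the hypothesis with minimum chi-square.

    Returns ``(label, ambiguous)``; the flag is set when the two best
    chi-squares differ by less than ``ambiguity`` (relative).
    """
    if not fits:
        raise ValueError("no hypothesis fits supplied")
    ordered = sorted(fits, key=lambda hc: hc[1])
    label = ordered[0][0]
    ambiguous = False
    if len(ordered) > 1:
        best, second = ordered[0][1], ordered[1][1]
        ambiguous = (second - best) < ambiguity * max(best, 1e-300)
    return label, ambiguous
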
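"""File readers/writers, run configuration and the pipeline driver.

Length units are Angstrom and momentum transfer A^-1 throughout; readers
convert nm columns at the boundary when a units row says so.  All
readers reject malformed input (naming the offending line) rather than
silently coercing it, and the run configuration uses a strict schema —
unknown keys are errors — to protect long analysis chains.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .laxs import DiffuseMap

logger = logging.getLogger("membranescatter")

__all__ = [
    "read_xy_table",
    "write_xy_table",
    "read_detector_tiff",
    "read_geometry",
    "RunConfig",
    "run_pipeline",
]


def read_xy_table(path: str | Path, expected_columns: tuple[str, ...] | None = None,
                  min_columns: int = 2, require_increasing: bool = True):
    """Parse a CSV or whitespace-delimited numeric table.

    An optional header row names the columns; an optional units row
    (e.g. ``nm``/``A``) immediately after it is honored: a first column
    in nm is converted to A.  Returns ``(names, columns)`` with one
    float array per column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    names: list[str] | None = None
    rows: list[list[float]] = []
    scale_first = 1.0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        try:
            rows.append([float(p) for p in parts])
            continue
        except ValueError:
            pass
        if names is None and not rows:
            names = parts
        elif not rows and names is not None:
            # units row
            if parts[0].lower() in ("nm",):
                scale_first = 10.0
        else:
            bad = next(p for p in parts if not _is_float(p))
            raise ValueError(f"{path.name}: non-numeric value {bad!r} on line {lineno}")
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"{path.name}: inconsistent column count on data row {i + 1}")
    if width < min_columns:
        raise ValueError(f"{path.name}: expected at least {min_columns} columns, got {width}")
    data = np.asarray(rows, dtype=float)
    data[:, 0] *= scale_first
    if require_increasing and np.any(np.diff(data[:, 0]) <= 0):
        raise ValueError(f"{path.name}: first column must be strictly increasing")
    if names is None:
        names = list(expected_columns[:width]) if expected_columns else \
            [f"col{i}" for i in range(width)]
    return names[:width], [data[:, i] for i in range(width)]


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_xy_table(path: str | Path, names: list[str], columns: list[np.ndarray]):
    path = Path(path)
    arr = np.column_stack(columns)
    header = ",".join(names)
    body = "\n".join(",".join(f"{v:.10g}" for v in row) for row in arr)
    path.write_text(header + "\n" + body + "\n")


_REQUIRED_GEOMETRY = ("wavelength_A", "distance_mm", "pixel_mm", "beam_center")


def read_geometry(path: str | Path) -> dict:
    geo = yaml.safe_load(Path(path).read_text())
    missing = [k for k in _REQUIRED_GEOMETRY if k not in geo]
    if missing:
        raise ValueError(f"geometry file missing fields: {', '.join(missing)}")
    return geo


def read_detector_tiff(path: str | Path, geometry: dict, symmetrize: bool = True) -> DiffuseMap:
    """Map a detector image (counts) onto a (q_r, q_z) grid.

    Pixel (row j, column i) at distances ``dx, dz`` from the beam center
    on a flat detector at distance L maps to q = (2 pi / lambda) *
    (k_out - k_in); the returned axes are evaluated along the beam-center
    row/column.  Row index increases downward in the image while q_z
    increases upward.  With ``symmetrize=True`` the left and right halves
    are averaged and the q_r >= 0 half map is returned.
    """
    import tifffile

    missing = [k for k in _REQUIRED_GEOMETRY if k not in geometry]
    if missing:
        raise ValueError(f"geometry missing fields: {', '.join(missing)}")
    img = tifffile.imread(str(path)).astype(float)
    lam = float(geometry["wavelength_A"])
    dist_a = float(geometry["distance_mm"]) * 1e7  # mm -> A
    pix_a = float(geometry["pixel_mm"]) * 1e7
    cx, cz = geometry["beam_center"]  # column, row of the direct beam
    n_rows, n_cols = img.shape
    k0 = 2.0 * np.pi / lam

    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    dx = (cols - cx) * pix_a
    dz = (cz - rows) * pix_a
    q_r_axis = k0 * dx / np.hypot(dx, dist_a)
    q_z_axis = k0 * dz / np.hypot(dz, dist_a)

    # orient so both axes increase
    img = img[::-1, :]
    q_z_axis = q_z_axis[::-1]
    if symmetrize:
        ic = int(round(cx))
        right = img[:, ic:]
        left = img[:, ic::-1]
        n = min(right.shape[1], left.shape[1])
        sym = 0.5 * (right[:, :n] + left[:, :n])
        return DiffuseMap(q_r_axis[ic:ic + n], q_z_axis, sym, geometry=dict(geometry))
    return DiffuseMap(q_r_axis, q_z_axis, img, geometry=dict(geometry))


class RunConfig(BaseModel):
    """Strict run configuration for one pipeline stage."""

    model_config = ConfigDict(extra="forbid")

    stage: Literal["props", "cd-fit", "laxs-fit", "waxs-fit", "sdp-fit", "simulate"]
    inputs: dict[str, str] = {}
    output_dir: str = "."
    params: dict[str, Any] = {}
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer, np.bool_)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    raise TypeError(f"not JSON serializable: {type(v)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage and write outputs plus a provenance record.

    Returns a result dict including ``outputs`` (paths written) and
    ``converged`` where applicable; nonconvergence is reported, never
    silent.  Identical configurations produce byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, p in config.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r}: no such file {p}")

    handler = _STAGES[config.stage]
    result = handler(config, out_dir)

    prov = {
        "stage": config.stage,
        "package_version": __version__,
        "seed": config.seed,
        "params": config.params,
        "inputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                   for k, v in config.inputs.items()},
        "outputs": result.get("outputs", []),
    }
    prov_path = out_dir / f"{config.stage.replace('-', '_')}_provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True, default=_json_default))
    result.setdefault("provenance", str(prov_path))
    return result


# ---------------------------------------------------------------------------
# stage handlers


def _stage_props(config: RunConfig, out_dir: Path) -> dict:
    from .peptides import ResidueScale, fauchere_pliska_scale, parse_sequence

    p = config.params
    rec = parse_sequence(p["seq"], name=p.get("name", "peptide"))
    if "scale_yaml" in p:
        raw = yaml.safe_load(Path(p["scale_yaml"]).read_text())
        scale = ResidueScale(
            name=p.get("scale_name", "user"),
            hydrophobicity={k: float(v["h"]) for k, v in raw.items()},
            charge={k: int(v.get("charge", 0)) for k, v in raw.items()},
        )
    else:
        scale = fauchere_pliska_scale(h_nva=p.get("h_nva"), h_tic=p.get("h_tic"))
    from .peptides import hydrophobic_moment, mean_hydrophobicity, net_charge

    out = out_dir / "props.csv"

    def _half_up(x, nd):  # table-style rounding (0.3625 -> 0.363)
        from decimal import ROUND_HALF_UP, Decimal
        q = Decimal(10) ** -nd
        return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

    charge = net_charge(rec, scale)
    result = {"name": rec.name, "length": rec.length, "net_charge": charge}
    covered = all(c in scale.hydrophobicity for c in rec.residues)
    if covered:
        h_val = mean_hydrophobicity(rec, scale)
        mu_val = hydrophobic_moment(rec, scale, delta_deg=float(p.get("delta", 100.0)))
        h = _half_up(h_val, 3)
        mu = _half_up(mu_val, 3)
        ratio = _half_up(mu_val / h_val, 2) if h_val != 0 else ""
        result.update(mean_hydrophobicity=h_val, hydrophobic_moment=mu_val)
    else:
        # H/muH are undefined until the user supplies values for the
        # unnatural residues; report the sequence-derived columns only
        h = mu = ratio = ""
    out.write_text(
        "name,n_residues,charge,muH,H,muH_over_H\n"
        f"{rec.name},{rec.length},{charge:+d},{mu},{h},{ratio}\n"
    )
    return {"outputs": [str(out)], "properties": result}


def _stage_cd_fit(config: RunConfig, out_dir: Path) -> dict:
    from .cd import (BasisSet, MRESpectrum, MotifFractionFitter, default_basis,
                     ellipticity_to_mre)

    p = config.params
    names, cols = read_xy_table(config.inputs["spectrum"])
    wl = cols[0]
    n_res = int(p.get("n_residues", 1))
    if names[1].lower().startswith("mre"):
        mre = cols[1]
    else:
        mre = ellipticity_to_mre(cols[1], n_res)
    if "basis" in config.inputs:
        bn, bc = read_xy_table(config.inputs["basis"], min_columns=5)
        basis = BasisSet(bc[0], np.column_stack(bc[1:5]))
    else:
        basis = default_basis(wl)
    est = MotifFractionFitter(basis=basis, weights=p.get("weights"),
                              fixed_ab_ratio=p.get("fix_ab_ratio"))
    est.fit(MRESpectrum(wl, mre, n_residues=n_res), None)
    out = out_dir / "cd_fit.json"
    out.write_text(json.dumps(asdict(est.result_), indent=2, default=_json_default))
    fit_csv = out_dir / "cd_fit_curve.csv"
    write_xy_table(fit_csv, ["wavelength_nm", "mre", "mre_fit"], [wl, mre, est.fitted_mre_])
    return {"outputs": [str(out), str(fit_csv)], "fractions": est.fractions_.tolist(),
            "converged": True}


def _stage_waxs_fit(config: RunConfig, out_dir: Path) -> dict:
    from .waxs import AngularProfile, ChainOrderFitter

    p = config.params
    _, cols = read_xy_table(config.inputs["profile"])
    phi, inten = cols[0], cols[1]
    keep = np.ones_like(phi, dtype=bool)
    if "phi_min" in p:
        keep &= phi >= float(p["phi_min"])
    if "phi_max" in p:
        keep &= phi <= float(p["phi_max"])
    est = ChainOrderFitter().fit(AngularProfile(phi[keep], inten[keep]))
    out = out_dir / "waxs_fit.json"
    out.write_text(json.dumps(asdict(est.result_), indent=2, default=_json_default))
    return {"outputs": [str(out)], "converged": est.converged_,
            "s_xray": est.s_xray_, "m": est.m_}


def _read_map(config: RunConfig) -> DiffuseMap:
    if "map_tiff" in config.inputs:
        geo = read_geometry(config.inputs["geometry"])
        return read_detector_tiff(config.inputs["map_tiff"], geo)
    _, cols = read_xy_table(config.inputs["map"], min_columns=3,
                            require_increasing=False)
    qr_u = np.unique(cols[0])
    qz_u = np.unique(cols[1])
    if qr_u.size * qz_u.size != cols[2].size:
        raise ValueError("gridded map text must cover a full q_r x q_z grid")
    inten = np.full((qz_u.size, qr_u.size), np.nan)
    iz = np.searchsorted(qz_u, cols[1])
    ir = np.searchsorted(qr_u, cols[0])
    inten[iz, ir] = cols[2]
    if np.any(np.isnan(inten)):
        raise ValueError("gridded map text has missing grid points")
    return DiffuseMap(qr_u, qz_u, inten)


def _stage_laxs_fit(config: RunConfig, out_dir: Path) -> dict:
    from .laxs import ElasticityFitter, StackParameters

    p = config.params
    data = _read_map(config)
    _, fcols = read_xy_table(config.inputs["form_factor"])
    ff = np.interp(data.q_z, fcols[0], fcols[1])
    init = StackParameters(
        kc=float(p.get("init_kc", 20.0)), b=float(p.get("init_b", 1e-3)),
        n_layers=int(p.get("n_layers", 100)),
        domain_lr=float(p.get("domain_lr", 2500.0)),
        d_spacing=float(p.get("d_spacing", 64.0)),
        temperature=float(p.get("temperature", 310.15)),
    )
    est = ElasticityFitter(init, qr_min=float(p.get("qr_min", 3e-3)),
                           n_starts=int(p.get("n_starts", 3)), seed=config.seed)
    est.fit(data, ff)
    out = out_dir / "laxs_fit.json"
    out.write_text(json.dumps(asdict(est.result_), indent=2, default=_json_default))
    return {"outputs": [str(out)], "converged": est.converged_,
            "kc": est.kc_, "b": est.b_}


def _stage_sdp_fit(config: RunConfig, out_dir: Path) -> dict:
    from .sdp import (FormFactorData, FormFactorFitter, PeptideEnvelope,
                      SDPParams, default_composition, load_compositions,
                      select_peptide_location)

    p = config.params
    _, cols = read_xy_table(config.inputs["form_factor"])
    sigma = cols[2] if len(cols) > 2 else None
    data = FormFactorData(cols[0], cols[1], sigma)
    comps = load_compositions(config.inputs.get("composition"))
    comp = comps[p.get("composition", "gneg_im")] if isinstance(comps, dict) else comps
    init = SDPParams(a_l=float(p.get("a_l", 71.0)))
    pep = None
    if "peptide" in p:
        pp = p["peptide"]
        pep = PeptideEnvelope(volume=float(pp["volume"]), electrons=float(pp["electrons"]),
                              lipid_per_peptide=float(pp["lipid_per_peptide"]),
                              center=15.0, width=3.0)
    hypo = p.get("hypothesis", "none")
    hypos = ["none", "headgroup", "hydrocarbon", "both"] if hypo == "all" else [hypo]
    results = {}
    fits = []
    for h in hypos:
        if h != "none" and pep is None:
            continue
        est = FormFactorFitter(comp, init, pep, hypothesis=h).fit(data)
        results[h] = {"chi2": est.chi2_, "summary": asdict(est.summary_),
                      "converged": est.converged_}
        fits.append((h, est.chi2_, est))
    label, ambiguous = select_peptide_location([(h, c) for h, c, _ in fits])
    best = next(e for h, c, e in fits if h == label)
    out = out_dir / "sdp_fit.json"
    out.write_text(json.dumps(
        {"selected": label, "ambiguous": ambiguous, "fits": results},
        indent=2, default=_json_default))
    rho, comps_d = best.model_.electron_density()
    edp = out_dir / "sdp_edp.csv"
    write_xy_table(edp, ["z_A", "total"] + list(comps_d),
                   [best.model_.z, rho] + list(comps_d.values()))
    return {"outputs": [str(out), str(edp)], "selected": label,
            "converged": all(r["converged"] for r in results.values())}


def _stage_simulate(config: RunConfig, out_dir: Path) -> dict:
    from .cd import default_basis
    from .laxs import StackParameters
    from .sdp import SDPModel, SDPParams, default_composition
    from .synthetic import (gen_cd_spectrum, gen_diffuse_map, gen_form_factor,
                            gen_waxs_profile)

    p = dict(config.params)
    what = p.pop("what")
    seed = config.seed
    outputs = []
    if what == "cd":
        basis = default_basis()
        spec, bundle = gen_cd_spectrum(p.get("fractions", [0.62, 0.10, 0.08, 0.20]),
                                       basis, p.get("noise_sd", 0.02), seed)
        f = out_dir / "cd_spectrum.csv"
        write_xy_table(f, ["wavelength_nm", "mre"], [spec.wavelength_nm, spec.mre])
        outputs.append(str(f))
    elif what == "waxs":
        prof, bundle = gen_waxs_profile(p.get("m", 6.0), p.get("scale", 100.0),
                                        p.get("baseline", 5.0), p.get("noise_sd", 0.02), seed)
        f = out_dir / "waxs_profile.csv"
        write_xy_table(f, ["phi_deg", "intensity"], [prof.phi_deg, prof.intensity])
        outputs.append(str(f))
    elif what == "form_factor":
        model = SDPModel(default_composition(p.get("composition", "gneg_im")),
                         SDPParams(a_l=p.get("a_l", 71.0)))
        qz = np.arange(0.02, 0.80, 0.005)
        data, bundle = gen_form_factor(model, qz, p.get("noise_sd", 0.02), seed)
        f = out_dir / "form_factor.csv"
        write_xy_table(f, ["q_z", "F", "sigma"], [data.q_z, data.f, data.sigma])
        outputs.append(str(f))
    elif what == "laxs":
        model = SDPModel(default_composition(p.get("composition", "gneg_im")),
                         SDPParams(a_l=p.get("a_l", 71.0)))
        sp = StackParameters(kc=p.get("kc", 20.0), b=p.get("b", 1e-3),
                             n_layers=int(p.get("n_layers", 100)),
                             d_spacing=p.get("d_spacing", 64.0))
        qr = np.linspace(1e-3, 0.15, int(p.get("n_qr", 80)))
        qz = np.linspace(0.10, 0.45, int(p.get("n_qz", 80)))
        ff = model.form_factor(qz)
        data, bundle = gen_diffuse_map(sp, ff, qr, qz, p.get("noise_level", 0.05), seed)
        f = out_dir / "diffuse_map.csv"
        qr_g, qz_g = np.meshgrid(data.q_r, data.q_z)
        write_xy_table(f, ["q_r", "q_z", "intensity"],
                       [qr_g.ravel(), qz_g.ravel(), data.intensity.ravel()])
        outputs.append(str(f))
        fff = out_dir / "form_factor.csv"
        write_xy_table(fff, ["q_z", "F"], [qz, ff])
        outputs.append(str(fff))
    else:
        raise ValueError(f"unknown simulation target {what!r}")
    bpath = out_dir / f"{what}_bundle.json"
    bpath.write_text(bundle.to_json())
    outputs.append(str(bpath))
    return {"outputs": outputs, "converged": True}


_STAGES = {
    "props": _stage_props,
    "cd-fit": _stage_cd_fit,
    "waxs-fit": _stage_waxs_fit,
    "laxs-fit": _stage_laxs_fit,
    "sdp-fit": _stage_sdp_fit,
    "simulate": _stage_simulate,
}
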
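"""File formats, configuration and the end-to-end analysis pipeline.

Formats
-------
* Distribution CSV: ``label, assay, dose_total_mGy, dose_np_mGy,
  dose_gamma_mGy, n0, n1, n2, ...`` — one row per dose point, ragged
  multiplicity columns allowed (missing treated as 0).
* Spectrum text: two columns (bin upper edge in keV/um, counts per source
  particle) after a header line ``# particle=<neutron|gamma> fluence=<phi>
  y_min=<first lower edge>``.
* Reports: JSON.

Doses are mGy at every file boundary; conversion to Gy happens only
inside curve fitting.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aberration import AberrationDistribution, summarize_distribution
from .dose_response import (
    DoseResponseCurve,
    fit_dose_response,
    points_from_distributions,
)
from .errors import PipelineError, SchemaError
from .microdosimetry import (
    FluencePair,
    PulseHeightSpectrum,
    combine_spectra,
    hit_distribution,
    summarize_spectrum,
)
from .rbe import rbe_max
from . import tables

__all__ = [
    "AnalysisConfig",
    "read_distribution_csv",
    "write_distribution_csv",
    "read_spectrum",
    "write_spectrum",
    "run_pipeline",
    "stats_records",
]

_REQUIRED_COLUMNS = ("label", "assay", "dose_total_mGy", "dose_np_mGy",
                     "dose_gamma_mGy")


def read_distribution_csv(path) -> list[AberrationDistribution]:
    """Parse a distribution CSV into typed objects.

    Multiplicity columns are ``n0, n1, ...``; ragged rows are densified
    with zeros.  Malformed rows raise with the offending line number.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    ncols = sorted(
        (c for c in df.columns if c.startswith("n") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not ncols:
        raise SchemaError(f"{path}: no multiplicity columns (n0, n1, ...)")
    dists = []
    for idx, row in df.iterrows():
        counts = np.array(
            [0 if pd.isna(row[c]) else int(row[c]) for c in ncols], dtype=np.int64
        )
        try:
            dists.append(AberrationDistribution(
                label=str(row["label"]),
                assay=str(row["assay"]),
                dose_total_mGy=float(row["dose_total_mGy"]),
                dose_np_mGy=float(row["dose_np_mGy"]),
                dose_gamma_mGy=float(row["dose_gamma_mGy"]),
                counts=counts,
            ))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {idx + 2}: {exc}") from exc
    return dists


def write_distribution_csv(dists: Sequence[AberrationDistribution], path) -> None:
    kmax = max(d.counts.size for d in dists)
    rows = []
    for d in dists:
        row = dict(label=d.label, assay=d.assay,
                   dose_total_mGy=d.dose_total_mGy, dose_np_mGy=d.dose_np_mGy,
                   dose_gamma_mGy=d.dose_gamma_mGy)
        for k in range(kmax):
            row[f"n{k}"] = int(d.counts[k]) if k < d.counts.size else 0
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectrum(path) -> tuple[PulseHeightSpectrum, float]:
    """Read a two-column spectrum file; returns (spectrum, fluence)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise SchemaError(f"{path}: missing '# particle=... fluence=...' header")
    header = dict(
        token.split("=", 1)
        for token in lines[0].lstrip("# ").split()
        if "=" in token
    )
    try:
        particle = header["particle"]
        fluence = float(header["fluence"])
        y_min = float(header["y_min"])
    except KeyError as exc:
        raise SchemaError(f"{path}: header missing field {exc}") from exc
    data = np.loadtxt(lines[1:], ndmin=2)
    if data.shape[1] != 2:
        raise SchemaError(f"{path}: expected two columns (upper edge, counts)")
    edges = np.concatenate([[y_min], data[:, 0]])
    return PulseHeightSpectrum(edges, data[:, 1], particle), fluence


def write_spectrum(spec: PulseHeightSpectrum, fluence: float, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# particle={spec.particle} fluence={fluence:.6g} "
            f"y_min={spec.bin_edges[0]:.6g}\n"
        )
        for hi, c in zip(spec.bin_edges[1:], spec.counts):
            fh.write(f"{hi:.6g}\t{c:.10g}\n")


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end pipeline run."""

    distributions_csv: Optional[str] = None   # None -> bundled study tables
    assays: Sequence[str] = ("DCA", "MN")
    model: str = "linear"                     # "linear", "lq" or "both"
    reference_curves: Optional[dict] = None   # assay -> DoseResponseCurve
    diameter_um: float = 1.0
    density_g_cm3: float = 1.0
    neutron_spectrum: Optional[str] = None
    gamma_spectrum: Optional[str] = None
    microdose_doses_mGy: Sequence[float] = ()
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("linear", "lq", "both"):
            raise ValueError("model must be 'linear', 'lq' or 'both'")
        if self.distributions_csv and not Path(self.distributions_csv).exists():
            raise ValueError(f"no such file: {self.distributions_csv}")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        refs = raw.pop("reference_curves", None)
        cfg = cls(**raw)
        if refs:
            cfg.reference_curves = {
                assay: DoseResponseCurve(
                    model=spec.get("model", "linear"),
                    c=spec.get("c", 0.0),
                    alpha=spec["alpha"],
                    beta=spec.get("beta"),
                    se_c=spec.get("se_c", 0.0),
                    se_alpha=spec.get("se_alpha", 0.0),
                    se_beta=spec.get("se_beta"),
                    label=spec.get("label", assay),
                )
                for assay, spec in refs.items()
            }
        return cfg


def stats_records(dists: Sequence[AberrationDistribution]) -> list[dict]:
    """Distribution summaries as JSON-ready records (NaN -> None)."""
    recs = []
    for d in dists:
        s = summarize_distribution(d)
        recs.append(dict(
            label=d.label, assay=d.assay, dose_total_mGy=d.dose_total_mGy,
            dose_np_mGy=d.dose_np_mGy, dose_gamma_mGy=d.dose_gamma_mGy,
            cells=s.cells, total_aberrations=s.total_aberrations,
            total_sd=s.total_sd, yield_per_cell=s.yield_per_cell,
            variance=s.variance,
            dispersion_index=_none_if_nan(s.dispersion_index),
            u_statistic=_none_if_nan(s.u_statistic),
            overdispersed=s.overdispersed_flag,
        ))
    return recs


def _none_if_nan(x: float):
    return None if (x is None or math.isnan(x)) else x


def _curve_record(curve: DoseResponseCurve, diag) -> dict:
    return dict(
        model=curve.model, label=curve.label,
        c=curve.c, se_c=curve.se_c,
        alpha=curve.alpha, se_alpha=curve.se_alpha,
        beta=curve.beta, se_beta=curve.se_beta,
        cov=curve.cov.tolist() if curve.cov is not None else None,
        chi2=diag.chi2, dof=diag.dof,
        chi2_p=_none_if_nan(diag.p_value),
        r_squared=_none_if_nan(diag.r_squared),
        alpha_p=_none_if_nan(diag.alpha_p),
        beta_p=_none_if_nan(diag.beta_p) if diag.beta_p is not None else None,
    )


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run stats -> fit -> RBE (-> microdosimetry) and return the report.

    With no input CSV the bundled pooled study tables are analysed.  The
    report carries every per-stage output plus stage timings; reruns with
    the same config and seed are identical except for the timestamps.
    """
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()
                               if k != "reference_curves"},
                    "stages": {}}

    def _stage(name):
        report["stages"][name] = {"started_at": time.time()}
        return report["stages"][name]

    # ---- stats ----------------------------------------------------------
    st = _stage("stats")
    if config.distributions_csv:
        dists = read_distribution_csv(config.distributions_csv)
    else:
        dists = tables.dca_distributions() + tables.mn_distributions()
    dists = [d for d in dists if d.assay in config.assays]
    if not dists:
        raise PipelineError("stats: no distributions match the requested assays")
    report["stats"] = stats_records(dists)
    st["seconds"] = time.time() - st.pop("started_at")

    # ---- fits + RBE -----------------------------------------------------
    models = {"linear": ["linear"], "lq": ["linear_quadratic"],
              "both": ["linear", "linear_quadratic"]}[config.model]
    refs = config.reference_curves or tables.REFERENCE_CURVES
    report["fits"] = {}
    report["rbe"] = {}
    ft = _stage("fit")
    for assay in config.assays:
        sub = [d for d in dists if d.assay == assay]
        if len(sub) < 2:
            continue
        pts = points_from_distributions(sub)
        report["fits"][assay] = {}
        for model in models:
            try:
                curve, diag = fit_dose_response(pts, model, label=f"{assay} fit")
            except Exception as exc:
                raise PipelineError(
                    f"fit: {assay}/{model} failed on {len(pts)} points: {exc}"
                ) from exc
            report["fits"][assay][model] = _curve_record(curve, diag)
            if model == "linear" and assay in refs:
                ref = refs[assay]
                res = rbe_max(curve.alpha, curve.se_alpha,
                              ref.alpha, ref.se_alpha,
                              numerator_label=curve.label,
                              denominator_label=ref.label)
                report["rbe"][assay] = dict(
                    value=res.value, se=res.se, method=res.method,
                    reference=ref.label,
                )
    ft["seconds"] = time.time() - ft.pop("started_at")

    # ---- microdosimetry (optional) -------------------------------------
    if config.neutron_spectrum and config.gamma_spectrum:
        mt = _stage("microdosimetry")
        spec_n, phi_n = read_spectrum(config.neutron_spectrum)
        spec_g, phi_g = read_spectrum(config.gamma_spectrum)
        combined = combine_spectra(spec_n, spec_g, FluencePair(phi_n, phi_g))
        summary = summarize_spectrum(combined, config.diameter_um,
                                     config.density_g_cm3)
        hits = {}
        for dose in config.microdose_doses_mGy:
            h = hit_distribution(dose, summary.z_F_mGy)
            hits[str(dose)] = dict(N=h.N, p0=float(h.p[0]), p1=float(h.p[1]),
                                   p_multi=h.p_multi)
        report["microdosimetry"] = dict(
            y_F=summary.y_F, y_D=summary.y_D, q_bar=summary.q_bar,
            z_F_mGy=summary.z_F_mGy, hits=hits,
        )
        mt["seconds"] = time.time() - mt.pop("started_at")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def render_report_table(report: dict) -> str:
    """Human-readable summary table of a pipeline report."""
    lines = ["dose(mGy)  assay  cells  total  yield   disp    u"]
    for r in report["stats"]:
        disp = "  n/a" if r["dispersion_index"] is None else f"{r['dispersion_index']:5.2f}"
        u = "   n/a" if r["u_statistic"] is None else f"{r['u_statistic']:6.2f}"
        lines.append(
            f"{r['dose_total_mGy']:9.0f}  {r['assay']:5s}  {r['cells']:5d}  "
            f"{r['total_aberrations']:5d}  {r['yield_per_cell']:.3f}  {disp} {u}"
        )
    for assay, fits in report.get("fits", {}).items():
        for model, f in fits.items():
            beta = "" if f["beta"] is None else f" beta={f['beta']:.3f}±{f['se_beta']:.3f}"
            lines.append(
                f"{assay} {model}: c={f['c']:.4f}±{f['se_c']:.4f} "
                f"alpha={f['alpha']:.3f}±{f['se_alpha']:.3f}{beta} /Gy"
            )
    for assay, r in report.get("rbe", {}).items():
        lines.append(f"{assay} RBE_M = {r['value']:.1f} ± {r['se']:.1f} vs {r['reference']}")
    return "\n".join(lines)
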
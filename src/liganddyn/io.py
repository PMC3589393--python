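"""CSV/JSON readers and writers for the pipeline's table dialects.

CSV carries data tables, JSON carries reports, YAML carries config.
Every writer's output is re-readable by its paired reader, with rows
sorted so output is byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecaySeries, ExpFit
from .dosy import AttenuationCurve, DiffusionFit, GradientGeometry
from .hdx import HdxRecord
from .modelfree import RelaxationSet, SelectionResult


class ValidationError(ValueError):
    """Malformed input table; message carries row/column diagnostics."""


DECAY_COLUMNS = ["site_id", "experiment", "delay_s", "intensity", "sigma",
                 "replicate"]
RELAXATION_COLUMNS = ["site_id", "field_1H", "T1", "sigma_T1", "T2",
                      "sigma_T2", "NOE", "sigma_NOE", "T1rho", "sigma_T1rho"]
ATTENUATION_COLUMNS = ["peak_id", "gradient_fraction", "intensity"]
HDX_COLUMNS = ["condition", "time_min", "replicate", "observed_mass",
               "reference_mass", "perdeuterated_mass"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise ValidationError(f"{path}: no data rows")
    return frame


def read_decay_csv(path: str | Path) -> dict[tuple[str, str], DecaySeries]:
    """Decay table -> {(site_id, experiment): DecaySeries}.

    Rows with replicate > 0 become duplicate measurements.  NOE_sat /
    NOE_ref experiments are returned as single-point pseudo-series via
    ``read_noe_pairs`` instead and skipped here.
    """
    frame = _read_csv(path, DECAY_COLUMNS)
    out: dict[tuple[str, str], DecaySeries] = {}
    for (site, exp), grp in frame.groupby(["site_id", "experiment"],
                                          sort=True):
        if exp.startswith("NOE"):
            continue
        main = grp[grp["replicate"].fillna(0).astype(int) == 0]
        dups = grp[grp["replicate"].fillna(0).astype(int) > 0]
        if len(main) < 3:
            raise ValidationError(
                f"{path}: site {site!r} experiment {exp!r} has "
                f"{len(main)} primary points (need >= 3)")
        sigma = main["sigma"].to_numpy(dtype=float)
        sigma_arg = sigma if np.all(np.isfinite(sigma)) and np.all(sigma > 0) \
            else None
        try:
            out[(site, exp)] = DecaySeries(
                delays=main["delay_s"].to_numpy(dtype=float),
                intensities=main["intensity"].to_numpy(dtype=float),
                sigma=sigma_arg,
                duplicates=[(float(r.delay_s), float(r.intensity))
                            for r in dups.itertuples()],
                site_id=str(site), experiment=str(exp),
            )
        except ValueError as exc:
            raise ValidationError(
                f"{path}: site {site!r} experiment {exp!r}: {exc}") from exc
    return out


def read_noe_pairs(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """NOE_sat/NOE_ref rows -> {site_id: [(I_sat, I_ref), ...]} by replicate."""
    frame = _read_csv(path, DECAY_COLUMNS)
    out: dict[str, list[tuple[float, float]]] = {}
    noe = frame[frame["experiment"].isin(["NOE_sat", "NOE_ref"])]
    for site, grp in noe.groupby("site_id", sort=True):
        pairs = []
        wide = grp.pivot_table(index="replicate", columns="experiment",
                               values="intensity", aggfunc="first")
        for _, row in wide.sort_index().iterrows():
            if np.isfinite(row.get("NOE_sat", np.nan)) and \
               np.isfinite(row.get("NOE_ref", np.nan)):
                pairs.append((float(row["NOE_sat"]), float(row["NOE_ref"])))
        if pairs:
            out[str(site)] = pairs
    return out


def write_decay_csv(path: str | Path,
                    series: dict[tuple[str, str], DecaySeries],
                    noe_pairs: dict[str, list[tuple[float, float]]]
                    | None = None) -> None:
    rows = []
    for (site, exp) in sorted(series):
        s = series[(site, exp)]
        for j, (t, i) in enumerate(zip(s.delays, s.intensities)):
            sig = s.sigma[j] if s.sigma is not None else np.nan
            rows.append((site, exp, t, i, sig, 0))
        for t, i in s.duplicates:
            rows.append((site, exp, t, i, np.nan, 1))
    for site in sorted(noe_pairs or {}):
        for rep, (i_sat, i_ref) in enumerate(noe_pairs[site], start=1):
            rows.append((site, "NOE_sat", np.nan, i_sat, np.nan, rep))
            rows.append((site, "NOE_ref", np.nan, i_ref, np.nan, rep))
    pd.DataFrame(rows, columns=DECAY_COLUMNS).to_csv(path, index=False)


def read_relaxation_csv(path: str | Path) -> list[RelaxationSet]:
    frame = _read_csv(path, RELAXATION_COLUMNS)
    sets = []
    for idx, row in frame.iterrows():
        try:
            t1rho = float(row["T1rho"])
            s_t1rho = float(row["sigma_T1rho"])
            sets.append(RelaxationSet(
                T1=float(row["T1"]), sigma_T1=float(row["sigma_T1"]),
                T2=float(row["T2"]), sigma_T2=float(row["sigma_T2"]),
                NOE=float(row["NOE"]), sigma_NOE=float(row["sigma_NOE"]),
                T1rho=t1rho if np.isfinite(t1rho) else None,
                sigma_T1rho=s_t1rho if np.isfinite(s_t1rho) else None,
                field_1H=float(row["field_1H"]), site_id=str(row["site_id"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return sets


def write_relaxation_csv(path: str | Path, sets: list[RelaxationSet]) -> None:
    rows = [{
        "site_id": s.site_id, "field_1H": s.field_1H,
        "T1": s.T1, "sigma_T1": s.sigma_T1,
        "T2": s.T2, "sigma_T2": s.sigma_T2,
        "NOE": s.NOE, "sigma_NOE": s.sigma_NOE,
        "T1rho": s.T1rho if s.T1rho is not None else np.nan,
        "sigma_T1rho": s.sigma_T1rho if s.sigma_T1rho is not None else np.nan,
    } for s in sorted(sets, key=lambda s: s.site_id)]
    pd.DataFrame(rows, columns=RELAXATION_COLUMNS).to_csv(path, index=False)


def read_attenuation_csv(
    path: str | Path, geometry: GradientGeometry
) -> list[AttenuationCurve]:
    frame = _read_csv(path, ATTENUATION_COLUMNS)
    curves = []
    for peak, grp in frame.groupby("peak_id", sort=True):
        grp = grp.sort_values("gradient_fraction")
        fr = grp["gradient_fraction"].to_numpy(dtype=float)
        geo_fr = np.asarray(geometry.fractions)
        if len(fr) != len(geo_fr) or not np.allclose(fr, geo_fr, rtol=1e-6):
            raise ValidationError(
                f"{path}: peak {peak!r} gradient schedule does not match "
                f"the configured geometry")
        curves.append(AttenuationCurve(
            geometry=geometry,
            intensities=grp["intensity"].to_numpy(dtype=float),
            peak_id=str(peak)))
    return curves


def write_attenuation_csv(path: str | Path,
                          curves: list[AttenuationCurve]) -> None:
    rows = []
    for c in sorted(curves, key=lambda c: c.peak_id):
        for fr, i in zip(c.geometry.fractions, c.intensities):
            rows.append((c.peak_id, fr, i))
    pd.DataFrame(rows, columns=ATTENUATION_COLUMNS).to_csv(path, index=False)


def read_hdx_csv(path: str | Path) -> list[HdxRecord]:
    frame = _read_csv(path, HDX_COLUMNS)
    records = []
    for (cond, t), grp in frame.groupby(["condition", "time_min"], sort=True):
        perdeut = grp["perdeuterated_mass"].dropna()
        try:
            records.append(HdxRecord(
                condition=str(cond), time_in_D2O=float(t),
                replicate_masses=grp["observed_mass"].to_numpy(dtype=float),
                reference_mass_H=float(grp["reference_mass"].iloc[0]),
                perdeuterated_mass_obs=float(perdeut.iloc[0])
                if len(perdeut) else None,
            ))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: condition {cond!r} t={t}: {exc}") from exc
    return records


def write_hdx_csv(path: str | Path, records: list[HdxRecord]) -> None:
    rows = []
    for rec in sorted(records, key=lambda r: (r.time_in_D2O, r.condition)):
        for j, m in enumerate(rec.replicate_masses, start=1):
            rows.append((rec.condition, rec.time_in_D2O, j, m,
                         rec.reference_mass_H,
                         rec.perdeuterated_mass_obs
                         if rec.perdeuterated_mass_obs is not None
                         else np.nan))
    pd.DataFrame(rows, columns=HDX_COLUMNS).to_csv(path, index=False)


def selection_report(results: list[SelectionResult]) -> list[dict]:
    """JSON-ready per-site report mirroring a model-free summary table."""
    report = []
    for res in results:
        p = res.chosen.params
        sig = res.chosen.param_sigmas or {}
        report.append({
            "model": p.model_id,
            "S2": round(p.S2, 2),
            "Sf2": round(p.Sf2, 2),
            "Ss2": round(p.Ss2, 2),
            "tau_e_ps": int(round(p.tau_e * 1e12)),
            "Rex_per_s": round(p.R_ex, 1),
            "chi2": res.chosen.chi2,
            "aic": round(res.chosen.aic, 1),
            "param_sigmas": {k: round(v, 4) if k != "tau_e" else v
                             for k, v in sig.items()},
            "rex_override_applied": res.rex_override_applied,
            "t1rho_t2_ratio": res.t1rho_t2_ratio,
            "aic_all_models": {f.params.model_id: round(f.aic, 1)
                               for f in res.all_fits if f.converged},
        })
    return report


def write_json(path: str | Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True,
                  default=lambda o: o.item() if hasattr(o, "item") else str(o))
        fh.write("\n")
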
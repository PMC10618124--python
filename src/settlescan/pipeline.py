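"""End-to-end orchestration: simulate/ingest → derive → model → map → report.

``run_pipeline`` sequences the stages — synthetic survey generation (or
ingest of existing tables), flag derivation and individual-level expansion,
complete-case filtering, the sample-size check, stratified risk regressions,
and per-site LJC cluster detection over all event layers — and writes a
reproducible bundle (CSV tables, GeoJSON layers, manifest, markdown report).
All randomness flows from a single integer seed recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import SettlescanError
from .regression import FitResult, ModelSpec, prevalence, run_model
from .sample_size import SampleSizeParams, minimum_households
from .schema import derive_flags, expand_to_individuals, filter_complete_cases, validate_households
from .simulate import SimConfig, SurveyData, default_config, simulate
from .spatial import build_event_layers, cluster_table
from . import io as sio


@dataclass
class ClusterParams:
    k: int = 16
    nperm: int = 999
    alpha: float = 0.05
    fdr: bool = False


@dataclass
class Bundle:
    """In-memory results of one pipeline run plus the output directory."""

    out_dir: Path
    survey: SurveyData
    individuals: pd.DataFrame  # complete-case analysis rows
    dropped: int
    sample_size: dict
    fits: dict  # stratum -> FitResult
    clusters: pd.DataFrame
    prevalences: pd.DataFrame
    manifest: dict


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_snapshot(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _config_snapshot(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _config_snapshot(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_snapshot(v) for v in obj]
    if hasattr(obj, "wkt"):  # shapely geometry
        return obj.wkt
    return obj


def run_pipeline(config: SimConfig | None = None, seed: int = 0,
                 out_dir=None, survey: SurveyData | None = None,
                 cluster_params: ClusterParams | None = None,
                 model_spec: ModelSpec | None = None,
                 write: bool = True) -> Bundle:
    """Execute the full analysis; returns the bundle (and writes it if asked)."""
    config = config or default_config()
    cluster_params = cluster_params or ClusterParams()
    base_spec = model_spec or ModelSpec()
    stage = "simulate"
    try:
        if survey is None:
            survey = simulate(config, seed=seed)
        stage = "validate"
        validate_households(survey.households, survey.individuals, survey.sites)
        stage = "derive/expand"
        flags = derive_flags(survey.households)
        rows = expand_to_individuals(survey.households, survey.individuals, flags)
        stage = "complete-cases"
        complete, dropped = filter_complete_cases(rows)
        stage = "samplesize"
        ss = minimum_households(SampleSizeParams())
        ss["enrolled_households"] = int(len(survey.households))
        ss["meets_minimum"] = bool(len(survey.households) >= ss["households"])
        stage = "regress"
        fits = {
            s: run_model(complete, dataclasses.replace(base_spec, stratum=s))
            for s in ("general", "under5")
        }
        stage = "clusters"
        cluster_parts = []
        for site in survey.sites:
            hh_site = survey.households.loc[
                survey.households["site_id"] == site.site_id].reset_index(drop=True)
            ind_site = survey.individuals.loc[
                survey.individuals["household_id"].isin(hh_site["household_id"])]
            layers = build_event_layers(hh_site, ind_site)
            cluster_parts.append(cluster_table(
                hh_site, layers, k=cluster_params.k, nperm=cluster_params.nperm,
                alpha=cluster_params.alpha, seed=seed, fdr=cluster_params.fdr))
        clusters = pd.concat(cluster_parts, ignore_index=True)
        stage = "prevalence"
        prev_rows = []
        for scope_site in [None] + [s.site_id for s in survey.sites]:
            for u5 in (None, True):
                try:
                    p = prevalence(rows, site=scope_site, under5=u5)
                except SettlescanError:
                    continue
                prev_rows.append({
                    "site": scope_site or "all",
                    "stratum": "under5" if u5 else "general",
                    "prevalence_pct": round(p, 1),
                })
        prevalences = pd.DataFrame(prev_rows)
    except Exception as exc:
        raise SettlescanError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "tool": "settlescan",
        "version": __version__,
        "seed": seed,
        "config": _config_snapshot(config),
        "cluster_params": dataclasses.asdict(cluster_params),
        "row_counts": {
            "households": int(len(survey.households)),
            "individuals": int(len(survey.individuals)),
            "analysis_rows": int(len(rows)),
            "complete_cases": int(len(complete)),
            "dropped_incomplete": int(dropped),
            "cluster_rows": int(len(clusters)),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    bundle = Bundle(out_dir=Path(out_dir) if out_dir else Path("."),
                    survey=survey, individuals=complete, dropped=dropped,
                    sample_size=ss, fits=fits, clusters=clusters,
                    prevalences=prevalences, manifest=manifest)
    if write and out_dir is not None:
        write_bundle(bundle)
    return bundle


def _fit_frame(fit: FitResult) -> pd.DataFrame:
    tab = fit.estimates.copy()
    tab.insert(0, "stratum", fit.stratum)
    tab["n"] = fit.n_rows
    tab["llr_p"] = fit.llr_p
    return tab


def write_bundle(bundle: Bundle) -> None:
    out = bundle.out_dir
    out.mkdir(parents=True, exist_ok=True)
    sio.write_households_csv(bundle.survey.households, out / "households.csv")
    sio.write_individuals_csv(bundle.survey.individuals, out / "individuals.csv")
    sio.write_households_geojson(bundle.survey.households, out / "households.geojson")
    sio.write_sites_geojson(bundle.survey.sites, out / "sites.geojson")
    for stratum, fit in bundle.fits.items():
        _fit_frame(fit).to_csv(out / f"aor_{stratum}.csv", index=False)
        if fit.screening is not None:
            fit.screening.to_csv(out / f"screening_{stratum}.csv", index=False)
    bundle.clusters.to_csv(out / "clusters.csv", index=False)
    for site in bundle.survey.sites:
        sub = bundle.clusters.loc[bundle.clusters["site_id"] == site.site_id]
        sio.write_clusters_geojson(
            sub, bundle.survey.households, out / f"clusters_{site.site_id}.geojson")
    bundle.prevalences.to_csv(out / "prevalence.csv", index=False)
    digests = {p.name: _digest(p) for p in sorted(out.glob("*.csv"))}
    manifest = dict(bundle.manifest, output_digests=digests)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.md").write_text(render_summary(bundle))


def render_summary(bundle: Bundle) -> str:
    """Human-readable markdown report regenerable from the bundle alone."""
    lines = ["# Survey analysis summary", ""]
    ss = bundle.sample_size
    lines += [
        f"Minimum sample: n0 = {ss['n0']:.1f} individuals → {ss['households']} households "
        f"(enrolled: {ss['enrolled_households']}; "
        f"{'meets' if ss['meets_minimum'] else 'BELOW'} the minimum).",
        "",
        "## Prevalence of diarrhea (past 2 weeks)", "",
        "| site | stratum | prevalence |", "|---|---|---|",
    ]
    for _, r in bundle.prevalences.iterrows():
        lines.append(f"| {r['site']} | {r['stratum']} | {r['prevalence_pct']:.1f}% |")
    for stratum, fit in bundle.fits.items():
        lines += ["", f"## Adjusted odds ratios — {stratum} "
                      f"(n = {fit.n_rows}, LLR p = {fit.llr_p:.3g})", "",
                  "| variable | aOR | 95% CI | stars | significant |", "|---|---|---|---|---|"]
        for _, r in fit.estimates.iterrows():
            lines.append(
                f"| {r['variable']} | {r['aOR']:.2f} | "
                f"{r['ci_low']:.2f}–{r['ci_high']:.2f} | {r['stars'] or '—'} | "
                f"{'yes' if r['significant'] else 'no'} |")
        if fit.screening is not None:
            dropped = fit.screening.loc[fit.screening["status"] != "kept"]
            for _, r in dropped.iterrows():
                lines.append(f"- excluded `{r['variable']}` ({r['status']}"
                             + (f": {r['note']}" if r["note"] else "") + ")")
    lines += ["", "## Spatial clusters (local join counts)", ""]
    if bundle.clusters.empty:
        lines.append("0 significant clusters (no event layers admitted inference).")
    else:
        counts = (bundle.clusters.groupby(["site_id", "layer"])["significant"]
                  .agg(["sum", "count"]))
        lines += ["| site | layer | significant / events |", "|---|---|---|"]
        for (site, layer), r in counts.iterrows():
            lines.append(f"| {site} | {layer} | {int(r['sum'])} / {int(r['count'])} |")
    lines += ["", f"_seed {bundle.manifest['seed']}, settlescan {bundle.manifest['version']}_", ""]
    return "\n".join(lines)
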
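"""Orchestration of the five analysis stages into one reproducible run.

A :class:`RunConfig` (YAML-serialisable, unknown keys rejected) names the
inputs and parameters of each stage; :func:`run` executes the enabled
stages and merges their outputs into one dossier per variant.  Dossiers
report evidence lines only — the stages stay independent and are never
auto-combined into a single pathogenicity call.  Every populated dossier
field carries a provenance key naming the stage that produced it, and a run
manifest records config and input hashes so identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__, cohort, conservation, metaclassifier, structgeo, trajstab

log = logging.getLogger("vuscope")

_STAGES = ("classifier", "conservation", "structgeo", "trajstab", "cohort")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_ALLOWED_KEYS = {
    "": {"seed", "output_dir", "stages", "classifier", "conservation",
         "structgeo", "trajstab", "cohort", "log_level"},
    "stages": set(_STAGES),
    "classifier": {"table", "thresholds"},
    "classifier.thresholds": {"high_coverage", "intermediate", "low_fpr"},
    "conservation": {"msa", "target_id", "positions", "high_threshold",
                     "moderate_threshold", "small_sample_correction"},
    "structgeo": {"pdb", "sites", "hbond_d_max", "salt_bridge_d_max",
                  "cation_pi_d_max", "cation_pi_angle_max", "his_as_cation",
                  "clash_radius", "clash_density_threshold"},
    "trajstab": {"analyses"},
    "cohort": {"table", "n_tested", "pedigrees", "published_summary"},
}


@dataclass
class RunConfig:
    """Validated run configuration with per-stage toggles and parameters."""

    seed: int = 0
    output_dir: str = "vuscope_out"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    classifier: dict = field(default_factory=dict)
    conservation: dict = field(default_factory=dict)
    structgeo: dict = field(default_factory=dict)
    trajstab: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        for s in self.stages:
            if s not in _STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        for section, allowed in _ALLOWED_KEYS.items():
            if section in ("", "stages"):
                continue
            sub = getattr(self, section.split(".")[0], {})
            if "." in section:
                sub = sub.get(section.split(".")[1], {}) or {}
            if isinstance(sub, dict):
                unknown = set(sub) - allowed
                if unknown and "." not in section:
                    raise ConfigError(
                        f"unknown keys in {section!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _ALLOWED_KEYS[""]
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _position_of(variant_id: str) -> Optional[int]:
    m = re.search(r"(\d+)", variant_id)
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# Stage runners: each returns {variant_id-or-"*": {field: value}}

def _run_classifier(cfg: dict) -> dict:
    table = metaclassifier.parse_predictor_table(cfg["table"])
    thr = metaclassifier.ModeThresholds(**(cfg.get("thresholds") or {}))
    out = {}
    for r in metaclassifier.classify_all(table, thr):
        out[r.variant_id] = {
            "n_benign": r.n_benign, "n_pathogenic": r.n_pathogenic,
            "n_na": r.n_na, "rate": f"{r.rate_2dp:.2f}",
            "verdicts": dict(r.verdict_per_mode),
        }
    return out


def _run_conservation(cfg: dict, variant_ids: list[str]) -> dict:
    aln = conservation.parse_alignment(cfg["msa"], cfg.get("target_id"))
    positions = cfg.get("positions")
    if positions is None:
        positions = [p for p in (_position_of(v) for v in variant_ids) if p]
    kwargs = {k: cfg[k] for k in ("high_threshold", "moderate_threshold")
              if k in cfg}
    out = {}
    for vid in variant_ids:
        pos = _position_of(vid)
        if pos is None or pos not in positions:
            continue
        try:
            col = conservation.map_residue_to_column(aln, pos)
        except IndexError:
            continue
        prof = conservation.column_profile(
            aln, col, cfg.get("small_sample_correction", False))
        out[vid] = {
            "position": pos, "column": col,
            "ref_residue": prof.ref_residue,
            "ref_frequency": round(prof.ref_frequency, 4),
            "info_bits": round(prof.info_bits, 3),
            "category": conservation.conservation_category(prof, **kwargs),
        }
    return out


def _run_structgeo(cfg: dict) -> dict:
    s = structgeo.parse_pdb(cfg["pdb"])
    hb = structgeo.find_hbonds(s, d_max=cfg.get("hbond_d_max", 3.5))
    sb = structgeo.find_salt_bridges(s, d_max=cfg.get("salt_bridge_d_max", 4.0))
    cp = structgeo.find_cation_pi(
        s, d_max=cfg.get("cation_pi_d_max", 6.0),
        angle_max=cfg.get("cation_pi_angle_max", 60.0),
        his_as_cation=cfg.get("his_as_cation", True))
    n_chains = len(set(s.chain_id[s.protein_mask].tolist()))
    out = {}
    for site in cfg.get("sites", []):
        vid = site["variant_id"]
        chain, rid = site["chain"], int(site["residue"])
        key = (chain, rid)
        involved = [r for r in hb + sb + cp
                    if r.partner_a[:2] == key or r.partner_b[:2] == key]
        exposure, burial = structgeo.relative_exposure(s, key)
        entry: dict[str, Any] = {
            "chain": chain, "residue": rid,
            "res_name": s.residue_name(chain, rid),
            "relative_exposure": round(exposure, 3), "burial": burial,
            "interactions": [
                {"kind": r.kind, "with": list(r.partner_b[:3])
                 if r.partner_a[:2] == key else list(r.partner_a[:3]),
                 "distance_A": round(r.distance, 2),
                 "interchain": r.interchain} for r in involved],
        }
        if n_chains >= 2:
            entry["min_interchain_distance_A"] = round(
                structgeo.min_interchain_distance(s, key), 2)
        if site.get("mutate_to"):
            rep = structgeo.substitution_clash_screen(
                s, key, site["mutate_to"],
                radius=cfg.get("clash_radius", 5.0),
                density_threshold=cfg.get("clash_density_threshold", 30))
            entry["clash_screen"] = {
                "new_residue": rep.new_residue,
                "delta_volume_A3": round(rep.delta_volume, 1),
                "neighbor_count": rep.neighbor_count,
                "potential_clash": rep.potential_clash,
            }
        out[vid] = entry
    return out


def _run_trajstab(cfg: dict) -> dict:
    out = {}
    for spec in cfg.get("analyses", []):
        vid = spec["variant_id"]
        site = (spec["site"][0], int(spec["site"][1]))
        verdicts, dimer_states = [], []
        for rep in spec["replicas"]:
            traj = trajstab.load_trajectory(
                rep["traj"], spec["reference"],
                replica_id=rep.get("replica_id", Path(rep["traj"]).stem))
            verdicts.extend(trajstab.analyze_replica(
                traj, site,
                radius_nm=spec.get("radius_nm", 1.0),
                cluster_cutoff=spec.get("cluster_cutoff", 0.15),
                stride=spec.get("stride", 1),
                window_fraction=spec.get("window_fraction", 0.25),
                outside_threshold=spec.get("outside_threshold", 0.5)))
            if spec.get("dimer", False):
                dimer_states.append(trajstab.dimer_state(traj))
        summary = trajstab.replica_summary(verdicts, dimer_states)
        out[vid] = {
            "replica_verdicts": [
                {"replica": v.replica_id, "chain": v.chain,
                 "verdict": v.verdict, "departure_frame": v.departure_frame}
                for v in verdicts],
            "stable_fraction": summary.fraction_text,
            "dimer_states": list(summary.dimer_states),
        }
    return out


def _run_cohort(cfg: dict) -> dict:
    records = cohort.load_cohort(cfg["table"])
    n_tested = int(cfg["n_tested"])
    summary: dict[str, Any] = {"n_records": len(records)}
    for cls in cohort.CLASSIFICATIONS:
        desc = cohort.describe(records, cls)
        desc["prevalence_pct"] = cohort.prevalence(records, n_tested, cls)
        summary[cls] = desc
    if cfg.get("published_summary"):
        published = json.loads(Path(cfg["published_summary"]).read_text())
        computed = {
            "plp_prevalence_pct": summary["P_LP"]["prevalence_pct"],
            "vus_prevalence_pct": summary["VUS"]["prevalence_pct"],
            "plp_mean_age": summary["P_LP"].get("mean_age"),
            "vus_mean_age": summary["VUS"].get("mean_age"),
        }
        summary["discrepancy_flags"] = cohort.flag_discrepancies(
            computed, published)
    coseg = {}
    for ped_path in cfg.get("pedigrees", []):
        ped = cohort.load_pedigree(ped_path)
        res = cohort.cosegregation(ped)
        coseg[ped.family_id] = {
            "variant": ped.variant, "verdict": res.verdict,
            "tested_affected_carriers": res.n_tested_affected_carriers,
            "tested_affected_noncarriers": res.n_tested_affected_noncarriers,
        }
    summary["cosegregation"] = coseg
    return summary


# ---------------------------------------------------------------------------

def run(config: RunConfig) -> dict:
    """Execute the enabled stages and write dossiers, TSV and manifest.

    Returns ``{"dossiers": {variant_id: dossier}, "manifest": {...}}``.
    Any stage failure aborts the run with the failing stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    outdir = Path(config.output_dir)
    (outdir / "dossiers").mkdir(parents=True, exist_ok=True)

    enabled = {s: config.stages.get(s, True) for s in _STAGES}
    results: dict[str, Any] = {}
    for stage, runner, args in (
            ("classifier", _run_classifier, (config.classifier,)),
            ("cohort", _run_cohort, (config.cohort,))):
        if enabled[stage] and getattr(config, stage):
            log.info("running stage %s with %s", stage, getattr(config, stage))
            try:
                results[stage] = runner(*args)
            except Exception as exc:
                raise StageError(stage, exc) from exc

    variant_ids = list(results.get("classifier", {}))
    for stage, runner in (("conservation", _run_conservation),
                          ("structgeo", _run_structgeo),
                          ("trajstab", _run_trajstab)):
        if enabled[stage] and getattr(config, stage):
            log.info("running stage %s", stage)
            try:
                if stage == "conservation":
                    results[stage] = runner(config.conservation, variant_ids)
                else:
                    results[stage] = runner(getattr(config, stage))
            except Exception as exc:
                raise StageError(stage, exc) from exc

    dossiers = {}
    for vid in variant_ids or sorted(
            set().union(*(results.get(s, {}) for s in
                          ("conservation", "structgeo", "trajstab")))):
        dossier: dict[str, Any] = {"variant_id": vid, "provenance": {}}
        for stage in ("classifier", "conservation", "structgeo", "trajstab"):
            if not enabled[stage] or not getattr(config, stage):
                dossier[stage] = "not-run"
                continue
            value = results.get(stage, {}).get(vid)
            dossier[stage] = value if value is not None else "no-data"
            if value is not None:
                dossier["provenance"][stage] = f"stage:{stage}"
        if enabled["cohort"] and config.cohort:
            dossier["cohort_context"] = results["cohort"]
            dossier["provenance"]["cohort_context"] = "stage:cohort"
        else:
            dossier["cohort_context"] = "not-run"
        dossiers[vid] = dossier
        (outdir / "dossiers" / f"{vid}.json").write_text(
            json.dumps(dossier, indent=2, sort_keys=True) + "\n")

    # flat TSV mirror
    rows = []
    for vid, d in dossiers.items():
        cls = d["classifier"] if isinstance(d["classifier"], dict) else {}
        cons = d["conservation"] if isinstance(d["conservation"], dict) else {}
        sg = d["structgeo"] if isinstance(d["structgeo"], dict) else {}
        tj = d["trajstab"] if isinstance(d["trajstab"], dict) else {}
        verdicts = cls.get("verdicts", {})
        rows.append("\t".join(str(x) for x in (
            vid, cls.get("rate", "NA"),
            verdicts.get("high_coverage", "NA"),
            verdicts.get("intermediate", "NA"),
            verdicts.get("low_fpr", "NA"),
            cons.get("category", "NA"),
            sg.get("burial", "NA"),
            tj.get("stable_fraction", "NA"),
            ",".join(tj.get("dimer_states", [])) or "NA")))
    header = ("variant_id\trate\tverdict_high_coverage\tverdict_intermediate"
              "\tverdict_low_fpr\tconservation\tburial\tstable_fraction"
              "\tdimer_states")
    (outdir / "dossiers.tsv").write_text("\n".join([header] + rows) + "\n")

    input_paths = []
    for section in (config.classifier, config.conservation, config.structgeo,
                    config.trajstab, config.cohort):
        for v in _iter_paths(section):
            input_paths.append(v)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "input_hashes": {str(p): _sha256_file(Path(p))
                         for p in sorted(set(input_paths))
                         if Path(p).is_file()},
        "stage_versions": {s: __version__ for s in _STAGES},
        "seed": config.seed,
        "n_dossiers": len(dossiers),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if enabled["cohort"] and config.cohort:
        (outdir / "cohort_summary.json").write_text(
            json.dumps(results["cohort"], indent=2, sort_keys=True) + "\n")
    return {"dossiers": dossiers, "manifest": manifest}


def _iter_paths(obj) -> list[str]:
    out = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if k in ("table", "msa", "pdb", "reference", "traj",
                     "published_summary"):
                out.append(v)
            elif k == "pedigrees":
                out.extend(v)
            else:
                out.extend(_iter_paths(v))
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            out.extend(_iter_paths(v))
    return out
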
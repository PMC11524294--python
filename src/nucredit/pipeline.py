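"""Pipeline orchestration: simulate -> call -> annotate -> enrich -> cluster
-> motif as one reproducible run, plus verification of the bundled
worked-example reference tables.

A run is described by a flat :class:`RunConfig` (round-trips to YAML); every
stage logs its inputs and writes its outputs under ``outdir``; the manifest
records parameter snapshot, per-file sha256 hashes and row counts so that
identical config + seed implies identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import caller as clr
from . import cluster as clu
from . import enrichment as enr
from . import io as nio
from . import motif as mot
from .simulate import SimConfig, simulate_all

_ALL_STAGES = ("simulate", "call", "annotate", "enrich", "cluster", "motif")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    outdir: str = "nucredit_run"
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    # generator scale
    n_transcripts: int = 80
    n_sites: int = 400
    coverage_mean: float = 100.0
    error_rate: float = 0.001
    motif_prob: float = 0.8
    n_samples: int = 30
    n_clusters: int = 3
    # caller thresholds
    min_coverage: int = 50
    min_base_quality: float = 20.0
    alpha: float = 0.05
    # clustering thresholds
    rho_threshold: float = 0.7
    cluster_p_threshold: float = 0.05
    # motif
    window: int = 5
    min_motif_sites: int = 20

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_transcripts=self.n_transcripts,
            n_sites=self.n_sites,
            coverage_mean=self.coverage_mean,
            error_rate=self.error_rate,
            motif_prob=self.motif_prob,
            n_samples=self.n_samples,
            n_clusters=self.n_clusters,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rows(path: Path) -> int:
    return sum(
        1 for line in path.read_text().splitlines() if line and not line.startswith("#")
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    manifest["config"]["stages"] = list(config.stages)

    def record(stage: str, t0: float, outputs: dict[str, Path], **extra) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "wall_time_s": round(time.monotonic() - t0, 3),
            "outputs": {
                k: {"sha256": _sha256(p), "rows": _rows(p)} for k, p in outputs.items()
            },
            **extra,
        }

    paths = {
        "fasta": outdir / "transcripts.fasta",
        "gff3": outdir / "regions.gff3",
        "pileup": outdir / "pileup.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "sites": outdir / "sites.tsv",
        "annotated": outdir / "annotated.tsv",
        "summary": outdir / "summary.json",
        "enrichment": outdir / "enrichment.tsv",
        "clusters": outdir / "clusters.tsv",
        "motif": outdir / "motif_report.tsv",
    }

    for stage in _ALL_STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.monotonic()
        if stage == "simulate":
            sim_paths = simulate_all(config.sim_config(), outdir)
            record(stage, t0, sim_paths)
        elif stage == "call":
            for need in ("fasta", "gff3", "pileup"):
                if not paths[need].exists():
                    raise FileNotFoundError(f"stage call: missing input {paths[need]}")
            transcripts = nio.read_transcripts(paths["fasta"], paths["gff3"])
            policy = clr.ReadFilterPolicy(
                min_coverage=config.min_coverage,
                min_base_quality=config.min_base_quality,
                alpha=config.alpha,
            )
            sites = clr.call_from_pileup(
                nio.read_pileup(paths["pileup"], transcripts), policy
            )
            nio.write_sites(sites, paths["sites"])
            record(stage, t0, {"sites": paths["sites"]}, n_sites=len(sites))
        elif stage == "annotate":
            if not paths["sites"].exists():
                raise FileNotFoundError("stage annotate: missing sites.tsv")
            transcripts = nio.read_transcripts(paths["fasta"], paths["gff3"])
            sites = ann.annotate_sites(nio.read_sites(paths["sites"]), transcripts)
            nio.write_sites(sites, paths["annotated"])
            summary = ann.summarize(sites, transcripts)
            evid_path = outdir / "evidence.tsv"
            if evid_path.exists():
                cv = ann.cross_validate(sites, nio.read_evidence(evid_path))
                summary["est_cross_validation"] = {
                    k: v for k, v in cv.items() if k != "per_transcript"
                }
            paths["summary"].write_text(
                json.dumps(_jsonable(summary), indent=1, sort_keys=True)
            )
            record(stage, t0, {"annotated": paths["annotated"]})
        elif stage == "enrich":
            if not (paths["labels"].exists() and paths["annotated"].exists()):
                raise FileNotFoundError("stage enrich: missing labels or annotated sites")
            labels = nio.read_labels(paths["labels"])
            edited = None
            if "edited" not in labels.columns:
                edited = {s.transcript_id for s in nio.read_sites(paths["annotated"])}
            go = enr.go_enrichment(labels, edited, alpha=config.alpha)
            endo = enr.endosymbiont_fisher(labels, edited)
            go.to_csv(paths["enrichment"], sep="\t", index=False)
            record(stage, t0, {"enrichment": paths["enrichment"]},
                   endosymbiont=endo)
        elif stage == "cluster":
            if not (paths["expression"].exists() and paths["annotated"].exists()):
                raise FileNotFoundError("stage cluster: missing expression or sites")
            expr = nio.read_expression(paths["expression"])
            sites = nio.read_sites(paths["annotated"])
            degrees = ann.mean_degrees(sites)
            adjusted = clu.adjust_expression(expr, degrees)
            est = clu.SCMCluster(
                rho_threshold=config.rho_threshold,
                p_threshold=config.cluster_p_threshold,
            ).fit(adjusted)
            rows = []
            for cid, cl in enumerate(est.clusters_, start=1):
                joined = {g: i for i, g in enumerate(cl.growth_trace)}
                for g in cl.members:
                    rows.append((cid, g, joined[g]))
            pd.DataFrame(
                rows, columns=["cluster", "gene", "join_order"]
            ).to_csv(paths["clusters"], sep="\t", index=False)
            record(stage, t0, {"clusters": paths["clusters"]},
                   n_clusters=len(est.clusters_))
        elif stage == "motif":
            if not paths["annotated"].exists():
                raise FileNotFoundError("stage motif: missing annotated sites")
            transcripts = nio.read_transcripts(paths["fasta"], paths["gff3"])
            sites = [
                s for s in nio.read_sites(paths["annotated"])
                if s.type_label == "C-to-U"
            ]
            background = mot.background_matrix(transcripts, config.window)
            groups: dict[str, list] = {"all": sites}
            if paths["clusters"].exists():
                membership = pd.read_csv(paths["clusters"], sep="\t")
                for cid, sub in membership.groupby("cluster"):
                    genes = set(sub["gene"])
                    groups[f"cluster_{cid}"] = [
                        s for s in sites if s.transcript_id in genes
                    ]
            rows = []
            for name, group_sites in groups.items():
                if len(group_sites) < config.min_motif_sites:
                    continue
                res = mot.scan_cluster(
                    group_sites, transcripts, background,
                    window=config.window, min_sites=config.min_motif_sites,
                )
                for t in res["tests"]:
                    counts = res["composition"].counts[:, t.position + config.window]
                    rows.append({
                        "group": name, "position": t.position,
                        "A": counts[0], "C": counts[1], "G": counts[2], "T": counts[3],
                        "chi2": t.chi2, "p": t.p_value,
                        "label": res["labels"][t.position],
                        "core_motif": res["core"],
                    })
            pd.DataFrame(rows).to_csv(paths["motif"], sep="\t", index=False)
            record(stage, t0, {"motif": paths["motif"]})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


# ------------------------------------------------------------- fixture checks

def load_reference_counts() -> dict:
    """Bundled reference count tables (see data/summary_counts.json)."""
    with resources.files("nucredit.data").joinpath("summary_counts.json").open() as fh:
        return json.load(fh)


def load_chloroplast_sites() -> pd.DataFrame:
    with resources.files("nucredit.data").joinpath("chloroplast_sites.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_cluster_counts() -> pd.DataFrame:
    with resources.files("nucredit.data").joinpath("cluster_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def compute_reference_checks() -> dict:
    """Recompute every worked-example quantity from the bundled raw tables.

    Each entry carries the recomputed value, the published value, and a pass
    flag; nothing is read from outside the installed package.
    """
    ref = load_reference_counts()
    chloro = load_chloroplast_sites()
    clusters = load_cluster_counts()
    checks: dict[str, dict] = {}

    def add(name, value, expected, places=6):
        checks[name] = {
            "value": value,
            "expected": expected,
            "pass": round(value - expected, places) == 0,
        }

    add("total_sites", sum(ref["region_site_counts"].values()), ref["total_sites"])
    add(
        "cds_four_type_total",
        sum(ref["cds_four_type_counts"].values()),
        ref["cds_four_type_total"],
    )
    endo = ref["endosymbiont"]
    add(
        "endosymbiont_edited_pct",
        round(100.0 * endo["edited"] / endo["total"], 1),
        endo["reported_pct"],
    )
    for short, ex in zip(("go_cul4_edited_pct", "go_exocyst_edited_pct"),
                         ref["go_examples"]):
        add(short, round(100.0 * ex["k_edited"] / ex["term_size"], 1),
            ex["reported_pct"])
    est = ref["est"]
    add("est_confirmed_pct",
        round(100.0 * est["confirmed"] / est["covered"], 1), est["reported_pct"])
    add(
        "chloroplast_second_codon_sites",
        int((chloro["codon_position"] == 2).sum()),
        ref["chloroplast"]["second_codon_position_sites"],
    )
    add(
        "chloroplast_c_to_u_sites",
        int(((chloro["dna"] == "C") & (chloro["rna"] == "T")).sum()),
        ref["chloroplast"]["c_to_u_sites"],
    )
    add("cluster_edited_gene_total", int(clusters["n_edited_genes"].sum()),
        ref["clusters"]["edited_gene_total"])
    add("cluster_ppr_total", int(clusters["n_ppr"].sum()),
        ref["clusters"]["ppr_total"])
    return checks


def verify_fixtures() -> tuple[bool, dict]:
    """Recompute all bundled worked-example quantities; (all_pass, report)."""
    checks = compute_reference_checks()
    return all(c["pass"] for c in checks.values()), checks
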
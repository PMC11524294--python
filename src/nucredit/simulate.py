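"""Synthetic-data generator for the whole pipeline.

Every input the analysis consumes can be generated here with the statistical
structure the downstream methods assume: transcript models with a 5'UTR / CDS /
3'UTR partition, per-position pileups with planted editing events at controlled
degrees plus uniform sequencing error, block-correlated PPR/target expression,
label tables with configurable per-stratum edited fractions, and a purine bias
at the -1/+1 flanks of planted C-to-U sites.

Reproducibility contract: each generator operation draws from its own RNG
stream seeded as ``config.seed + <fixed op offset>``, so adding operations
never perturbs the outputs of existing ones, and an identical seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .models import (
    BASES,
    EDITING_TYPES,
    EvidenceCall,
    PileupColumn,
    PlantedSite,
    TranscriptModel,
    type_to_bases,
)

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in _STOPS
)

# fixed per-operation RNG stream offsets (see module docstring)
_OP = {
    "transcripts": 1, "sites": 2, "pileup": 3, "expression": 4,
    "motif": 5, "annotations": 6, "evidence": 7, "roles": 8,
}


def _default_type_weights() -> dict[str, float]:
    # four dominant types carry 61.3% of sites, the remaining eight split the rest
    w = {t: 0.387 / 8 for t in EDITING_TYPES}
    for t in ("C-to-U", "U-to-C", "A-to-G", "G-to-A"):
        w[t] = 0.613 / 4
    return w


@dataclass
class SimConfig:
    """Knobs of the generator; defaults emulate the study conditions at desk scale."""

    n_transcripts: int = 80
    utr5_len: tuple[int, int] = (100, 300)
    cds_len: tuple[int, int] = (300, 900)
    utr3_len: tuple[int, int] = (150, 400)
    n_sites: int = 400
    editing_types: dict[str, float] = field(default_factory=_default_type_weights)
    degree_range: tuple[float, float] = (0.20, 0.65)
    coverage_mean: float = 100.0
    error_rate: float = 0.001
    motif_prob: float = 0.8
    n_samples: int = 30
    n_clusters: int = 3
    ppr_per_cluster: int = 3
    targets_per_cluster: int = 8
    within_cluster_rho: float = 0.8
    endo_fraction: float = 0.17
    edited_fraction_endo: float = 0.273
    edited_fraction_other: float = 0.195
    n_go_terms: int = 20
    go_term_prob: float = 0.05
    est_coverage_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "motif_prob", "endo_fraction",
                     "edited_fraction_endo", "edited_fraction_other",
                     "go_term_prob", "est_coverage_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        lo, hi = self.degree_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"degree_range {self.degree_range} outside [0,1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if any(w < 0 for w in self.editing_types.values()):
            raise ValueError("editing type weights must be non-negative")
        unknown = set(self.editing_types) - set(EDITING_TYPES)
        if unknown:
            raise ValueError(f"unknown editing types {sorted(unknown)}")

    def rng(self, op: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _OP[op])


# --------------------------------------------------------------- transcripts

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(BASES)[rng.integers(0, 4, n)])


def generate_transcripts(config: SimConfig) -> dict[str, TranscriptModel]:
    """Random transcript models: ATG-led CDS with no internal in-frame stop,
    terminated by a stop codon, flanked by UTRs of the configured lengths."""
    rng = config.rng("transcripts")
    if min(config.cds_len) < 9:
        raise ValueError("cds_len must allow at least 3 codons (start, body, stop)")
    out: dict[str, TranscriptModel] = {}
    width = max(4, len(str(config.n_transcripts)))
    for i in range(config.n_transcripts):
        tid = f"T{i + 1:0{width}d}"
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        lo_c, hi_c = config.cds_len[0] // 3, config.cds_len[1] // 3
        n_codons = int(rng.integers(lo_c, hi_c + 1))
        body = rng.choice(len(_SENSE_CODONS), n_codons - 2)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in body) + stop
        seq = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
        out[tid] = TranscriptModel(
            id=tid, sequence=seq,
            utr5=(0, u5), cds=(u5, u5 + len(cds)), utr3=(u5 + len(cds), len(seq)),
        )
    return out


# --------------------------------------------------------------------- sites

#: planted sites keep a clear ±5 flank so the motif scanner sees every site
FLANK_MARGIN = 5


def plant_sites(
    transcripts: dict[str, TranscriptModel], config: SimConfig
) -> list[PlantedSite]:
    """Plant ``n_sites`` editing events at distinct coordinates.

    The substitution type of each site is sampled from ``editing_types``; the
    site is then placed uniformly on a remaining position whose reference base
    matches the type. True degrees are uniform over ``degree_range``.
    """
    rng = config.rng("sites")
    pools: dict[str, list[tuple[str, int]]] = {b: [] for b in BASES}
    for tid in sorted(transcripts):
        t = transcripts[tid]
        for pos in range(FLANK_MARGIN, len(t) - FLANK_MARGIN):
            pools[t.sequence[pos]].append((tid, pos))
    total = sum(len(p) for p in pools.values())
    if config.n_sites > total:
        raise ValueError(f"n_sites={config.n_sites} exceeds {total} eligible positions")

    labels = sorted(config.editing_types)
    weights = np.array([config.editing_types[t] for t in labels], dtype=float)
    weights = weights / weights.sum()
    sites: list[PlantedSite] = []
    for _ in range(config.n_sites):
        # draw types until one with a free matching position remains
        for _attempt in range(1000):
            label = labels[int(rng.choice(len(labels), p=weights))]
            ref, alt = type_to_bases(label)
            if pools[ref]:
                break
        else:
            raise ValueError("could not place site: matching positions exhausted")
        pool = pools[ref]
        j = int(rng.integers(0, len(pool)))
        tid, pos = pool[j]
        pool[j] = pool[-1]
        pool.pop()
        degree = float(rng.uniform(*config.degree_range))
        sites.append(PlantedSite(tid, pos, ref, alt, degree))
    sites.sort(key=lambda s: (s.transcript_id, s.position))
    return sites


# --------------------------------------------------------------------- motif

def embed_motif_context(
    transcripts: dict[str, TranscriptModel],
    planted: list[PlantedSite],
    config: SimConfig,
) -> dict[str, TranscriptModel]:
    """Rewrite the -1/+1 flanks of planted C-to-U sites toward purines.

    With probability ``motif_prob`` both immediate neighbours of an eligible
    edited C are set to A or G (equal odds). Rewrites never touch another
    planted site's base, and rewrites inside a CDS are resampled if they would
    create an in-frame internal stop codon.
    """
    rng = config.rng("motif")
    planted_pos = {(s.transcript_id, s.position) for s in planted}
    seqs = {tid: list(t.sequence) for tid, t in transcripts.items()}

    def creates_internal_stop(t: TranscriptModel, seq: list[str]) -> bool:
        c0, c1 = t.cds
        cds = "".join(seq[c0:c1])
        return any(cds[k : k + 3] in _STOPS for k in range(0, len(cds) - 3, 3))

    for s in planted:
        if not (s.ref_base == "C" and s.alt_base == "T"):
            continue
        t = transcripts[s.transcript_id]
        if not FLANK_MARGIN <= s.position <= len(t) - 1 - FLANK_MARGIN:
            continue
        if rng.uniform() >= config.motif_prob:
            continue
        seq = seqs[s.transcript_id]
        targets = [
            p for p in (s.position - 1, s.position + 1)
            if (s.transcript_id, p) not in planted_pos
        ]
        if not targets:
            continue
        original = [seq[p] for p in targets]
        for _try in range(20):
            for p in targets:
                seq[p] = "AG"[int(rng.integers(0, 2))]
            if not creates_internal_stop(t, seq):
                break
        else:
            for p, b in zip(targets, original):
                seq[p] = b
    return {
        tid: replace(t, sequence="".join(seqs[tid])) for tid, t in transcripts.items()
    }


# -------------------------------------------------------------------- pileup

def simulate_pileup(
    transcripts: dict[str, TranscriptModel],
    planted: list[PlantedSite],
    config: SimConfig,
) -> list[PileupColumn]:
    """Per-position base counts: Poisson coverage (truncated at >=1) and a
    multinomial read-base draw with uniform error over the three non-reference
    bases, plus the planted degree at planted sites. Counts sum to coverage by
    construction."""
    rng = config.rng("pileup")
    e3 = config.error_rate / 3.0
    qual = 60.0 if config.error_rate == 0 else -10.0 * math.log10(config.error_rate)
    by_site = {(s.transcript_id, s.position): s for s in planted}

    columns: list[PileupColumn] = []
    for tid in sorted(transcripts):
        t = transcripts[tid]
        L = len(t)
        cov = rng.poisson(config.coverage_mean, L)
        while (zero := cov == 0).any():  # truncate at >= 1
            cov[zero] = rng.poisson(config.coverage_mean, int(zero.sum()))
        seq = t.sequence
        counts_mat = np.zeros((L, 4), dtype=np.int64)
        base_idx = {b: i for i, b in enumerate(BASES)}
        plain = []  # positions with pure error structure, grouped by ref base
        for pos in range(L):
            site = by_site.get((tid, pos))
            if site is None:
                plain.append(pos)
            else:
                p = np.full(4, e3)
                ai = base_idx[site.alt_base]
                ri = base_idx[site.ref_base]
                p[ai] = min(site.true_degree + e3, 1.0)
                p[ri] = 0.0
                p[ri] = max(1.0 - p.sum(), 0.0)
                counts_mat[pos] = rng.multinomial(cov[pos], p / p.sum())
        plain_arr = np.asarray(plain, dtype=np.int64)
        for b, ri in base_idx.items():
            pos_b = plain_arr[[seq[p] == b for p in plain]] if plain else plain_arr[:0]
            if len(pos_b) == 0:
                continue
            p = np.full(4, e3)
            p[ri] = 1.0 - config.error_rate
            counts_mat[pos_b] = rng.multinomial(cov[pos_b], p / p.sum())
        for pos in range(L):
            if seq[pos] == "N":
                continue
            columns.append(
                PileupColumn(
                    transcript_id=tid, position=pos, ref=seq[pos],
                    counts={b: int(counts_mat[pos, base_idx[b]]) for b in BASES},
                    mean_qual=qual,
                )
            )
    return columns


# ---------------------------------------------------------------- expression

def assign_roles(
    transcripts: dict[str, TranscriptModel],
    planted: list[PlantedSite],
    config: SimConfig,
) -> pd.DataFrame:
    """Assign PPR and C-to-U target roles to planted coexpression clusters.

    Targets are drawn from transcripts carrying at least one planted C-to-U
    site; PPR genes get fresh identifiers (they are regulators, not templates).
    Returns a frame indexed by gene with columns ``cluster`` and ``role``.
    """
    rng = config.rng("roles")
    ctu = sorted(
        {s.transcript_id for s in planted if (s.ref_base, s.alt_base) == ("C", "T")}
    )
    need = config.n_clusters * config.targets_per_cluster
    if len(ctu) < need:
        raise ValueError(
            f"{len(ctu)} C-to-U edited transcripts available but "
            f"{need} targets requested; raise n_sites or lower cluster sizes"
        )
    if config.ppr_per_cluster < 1 or config.targets_per_cluster < 3:
        raise ValueError("each cluster needs >=1 PPR and >=3 targets")
    chosen = rng.choice(len(ctu), size=need, replace=False)
    rows = []
    k = 0
    for c in range(1, config.n_clusters + 1):
        for _ in range(config.targets_per_cluster):
            rows.append((ctu[chosen[k]], c, "target"))
            k += 1
        for j in range(config.ppr_per_cluster):
            rows.append((f"PPR_c{c}_{j + 1}", c, "ppr"))
    df = pd.DataFrame(rows, columns=["gene", "cluster", "role"]).set_index("gene")
    return df


def simulate_expression(roles: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Block-correlated positive expression (log-normal around a per-cluster
    latent sample profile).

    The latent loading is chosen so the expected pairwise Spearman correlation
    within a cluster equals ``within_cluster_rho`` (via the Gaussian
    rank-correlation identity rho_s = (6/pi) arcsin(rho/2)); between-cluster
    correlations are centred at zero.
    """
    if config.n_samples < 5:
        raise ValueError("n_samples < 5: rank correlations would be unstable")
    rho_s = config.within_cluster_rho
    if not 0.0 <= rho_s <= 1.0:
        raise ValueError("within_cluster_rho outside [0,1]")
    pearson = 2.0 * math.sin(math.pi * rho_s / 6.0)
    a = math.sqrt(pearson)
    rng = config.rng("expression")
    samples = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    latent = {
        c: rng.standard_normal(config.n_samples) for c in sorted(roles["cluster"].unique())
    }
    data = np.empty((len(roles), config.n_samples))
    for i, (gene, row) in enumerate(roles.iterrows()):
        z = latent[row["cluster"]]
        x = a * z + math.sqrt(max(1.0 - a * a, 0.0)) * rng.standard_normal(
            config.n_samples
        )
        data[i] = np.exp(3.0 + x)  # positive scale, RPKM-like magnitudes
    return pd.DataFrame(data, index=roles.index.copy(), columns=samples)


# --------------------------------------------------------------- annotations

def simulate_annotations(
    gene_ids: list[str],
    config: SimConfig,
    edited: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Label table: GO terms, endosymbiont-derived flag and edited flag.

    Endosymbiont membership is Bernoulli(``endo_fraction``); the edited flag is
    Bernoulli with the configured per-stratum fraction (unless a ground-truth
    ``edited`` map is supplied); GO terms are assigned independently of both,
    so term-level enrichment p-values are null-calibrated by construction. The
    planted stratum odds ratio is exactly recoverable in expectation from
    ``edited_fraction_endo`` / ``edited_fraction_other``.
    """
    rng = config.rng("annotations")
    n = len(gene_ids)
    endo = rng.uniform(size=n) < config.endo_fraction
    if edited is None:
        frac = np.where(endo, config.edited_fraction_endo, config.edited_fraction_other)
        edited_flags = rng.uniform(size=n) < frac
    else:
        edited_flags = np.array([bool(edited.get(g, False)) for g in gene_ids])
    terms = [f"GO:{7000000 + k}" for k in range(config.n_go_terms)]
    member = rng.uniform(size=(n, config.n_go_terms)) < config.go_term_prob
    go_col = [
        ";".join(t for t, m in zip(terms, member[i]) if m) for i in range(n)
    ]
    return pd.DataFrame(
        {
            "go_terms": go_col,
            "endosymbiont": endo.astype(int),
            "ppr": [int(g.startswith("PPR_")) for g in gene_ids],
            "edited": edited_flags.astype(int),
        },
        index=pd.Index(gene_ids, name="gene"),
    )


# ------------------------------------------------------------------ evidence

def simulate_evidence(
    planted: list[PlantedSite], config: SimConfig
) -> list[EvidenceCall]:
    """EST-style single observations: each planted site is covered with
    probability ``est_coverage_prob``; a covered observation carries the edited
    base with probability equal to the site's true degree."""
    rng = config.rng("evidence")
    out = []
    for s in planted:
        if rng.uniform() < config.est_coverage_prob:
            base = s.alt_base if rng.uniform() < s.true_degree else s.ref_base
            out.append(EvidenceCall(s.transcript_id, s.position, base))
    return out


# ----------------------------------------------------------------- one-stop

def simulate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns the path map.

    Order matters: motif contexts are embedded before the pileup is drawn so
    that pileup reference bases match the final transcript sequences.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = generate_transcripts(config)
    planted = plant_sites(transcripts, config)
    transcripts = embed_motif_context(transcripts, planted, config)
    pileup = simulate_pileup(transcripts, planted, config)
    roles = assign_roles(transcripts, planted, config)
    expression = simulate_expression(roles, config)
    universe = sorted(transcripts) + [g for g in roles.index if str(g).startswith("PPR_")]
    labels = simulate_annotations(universe, config, edited=None)
    evidence = simulate_evidence(planted, config)

    paths = {
        "fasta": outdir / "transcripts.fasta",
        "gff3": outdir / "regions.gff3",
        "pileup": outdir / "pileup.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
        "evidence": outdir / "evidence.tsv",
        "roles": outdir / "roles.tsv",
    }
    nio.write_transcripts(transcripts.values(), paths["fasta"], paths["gff3"])
    nio.write_pileup(pileup, paths["pileup"])
    nio.write_expression(expression, paths["expression"])
    nio.write_labels(labels, paths["labels"])
    nio.write_truth(planted, paths["truth"])
    nio.write_evidence(evidence, paths["evidence"])
    roles.to_csv(paths["roles"], sep="\t")
    return paths
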
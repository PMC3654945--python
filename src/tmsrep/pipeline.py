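"""End-to-end orchestration: configuration, logging and staged runs.

Every run stage is a plain function over the library modules; the CLI is a
thin wrapper.  A run configuration is a flat key=value file; its digest is
embedded in every output so a result can always be traced to the exact
parameters that produced it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral, pairwise, repeat_scan, superfamily, superpose, synthetic, topology

log = logging.getLogger("tmsrep")

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_topology",
    "run_zscore",
    "run_repeat_scan",
    "run_network",
    "run_ancestor",
    "run_superpose",
]


@dataclass
class RunConfig:
    """Flat, serializable run parameters (defaults = the documented study
    settings: BLOSUM62, gap 8/2, z >= 10 over >= 60 residues, 1000 shuffles,
    90%/80% clustering cut-offs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 8.0
    gap_extend: float = 2.0
    z_min: float = 10.0
    min_span: int = 60
    tms_overlap_frac: float = 0.5
    n_shuffles: int = 1000
    cluster_identity: float = 0.9
    cluster_identity_secondary: float = 0.8
    caller_window: int = 13
    caller_tau: float = 0.65
    caller_min_len: int = 12
    caller_merge_gap: int = 8
    top_k: int = 50
    flank: int = 5
    seed: int = 0

    def scheme(self) -> pairwise.ScoringScheme:
        return pairwise.ScoringScheme(self.matrix, self.gap_open, self.gap_extend)

    def criteria(self) -> pairwise.HomologyCriteria:
        return pairwise.HomologyCriteria(self.z_min, self.min_span, self.tms_overlap_frac)

    def caller(self) -> dict:
        return {
            "w_h": self.caller_window,
            "tau": self.caller_tau,
            "min_len": self.caller_min_len,
            "merge_gap": self.caller_merge_gap,
        }

    def to_text(self) -> str:
        return "".join(f"{k}={v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                k = k.strip()
                if k not in casts:
                    raise ValueError(f"unknown config key {k!r}")
                typ = {"int": int, "float": float, "str": str}[casts[k]]
                kwargs[k] = typ(v.strip())
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def _stage_seed(config: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _header(config: RunConfig) -> str:
    return f"# tmsrep config_digest={config.digest()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_simulate(
    config: RunConfig, preset: str, n: int, d: float, outdir: Path, indel_rate: float = 1.0
) -> dict:
    """Generate a synthetic family; writes FASTA, truth TSV and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = synthetic.scenario_for_preset(
        preset, n=n, d=d, indel_rate=indel_rate, seed=_stage_seed(config, "simulate")
    )
    records, truths, manifest = synthetic.make_family(sc)
    synthetic.write_fasta(records, outdir / "family.fasta")
    synthetic.write_truth_tsv(truths, outdir / "truth.tsv")
    manifest["config_digest"] = config.digest()
    synthetic.write_manifest(manifest, outdir / "manifest.txt")
    log.info("simulated %d %s proteins into %s", n, preset, outdir)
    return manifest


def run_topology(config: RunConfig, fasta: Path, outdir: Path, plot: bool = False) -> None:
    """Profile and TMS-call every sequence; writes profile + annotation TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = synthetic.read_fasta(fasta)
    if not records:
        raise ValueError(f"no sequences in {fasta}")
    prof_rows, ann_rows = [], []
    for rec in records:
        prof = topology.profile(rec.seq, w_h=config.caller_window)
        ann = topology.call_tms(
            prof,
            tau=config.caller_tau,
            min_len=config.caller_min_len,
            merge_gap=config.caller_merge_gap,
        )
        for i, (h, a) in enumerate(zip(prof.hydropathy, prof.amphipathicity), start=1):
            prof_rows.append((rec.id, i, rec.seq[i - 1], h, a))
        for k, (lo, hi) in enumerate(ann.intervals, start=1):
            ann_rows.append((rec.id, k, lo, hi, ann.source))
        if plot:
            topology.plot_profile(rec.seq, ann, outdir / f"{rec.id}.png")
    _write_tsv(
        pd.DataFrame(prof_rows, columns=["id", "position", "residue", "H", "A"]),
        outdir / "profiles.tsv",
        config,
    )
    _write_tsv(
        pd.DataFrame(ann_rows, columns=["id", "tms_index", "start", "end", "source"]),
        outdir / "tms.tsv",
        config,
    )


def run_zscore(config: RunConfig, fasta: Path, outdir: Path) -> pd.DataFrame:
    """All-vs-all shuffle z-scores for the sequences of one FASTA file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = synthetic.read_fasta(fasta)
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    scheme = config.scheme()
    rows = []
    base = _stage_seed(config, "zscore")
    idx = 0
    for i, ra in enumerate(records):
        for rb in records[i + 1 :]:
            seed = int(np.random.SeedSequence([base, idx]).generate_state(1)[0] % 2**31)
            idx += 1
            score = pairwise.shuffle_zscore(ra.seq, rb.seq, scheme, config.n_shuffles, seed)
            aln = pairwise.global_align(ra.seq, rb.seq, scheme)
            rows.append(
                (ra.id, rb.id, score.quality, score.mu, score.sigma, score.z,
                 aln.aligned_pairs, aln.pct_identity, aln.pct_similarity, seed)
            )
    df = pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "Q", "mu", "sigma", "z", "aligned_pairs",
                 "pct_id", "pct_sim", "seed"],
    )
    _write_tsv(df, outdir / "zscores.tsv", config)
    return df


def run_repeat_scan(
    config: RunConfig,
    fasta: Path,
    split_after_tms: int,
    outdir: Path,
    annotations: Path | None = None,
) -> repeat_scan.ScanReport:
    """Cluster-reduce, annotate (if needed) and run the internal-repeat test."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = synthetic.read_fasta(fasta)
    if not records:
        raise ValueError(f"no sequences in {fasta}")
    reps, cluster_map = pairwise.cluster_reduce(
        [(r.id, r.seq) for r in records], config.cluster_identity, config.scheme()
    )
    kept = {rid for rid, _ in reps}
    records = [r for r in records if r.id in kept]
    log.info("cluster_reduce at %.0f%%: %d -> %d records",
             100 * config.cluster_identity, len(cluster_map), len(records))
    if annotations:
        ann_map = {
            pid: ivs for pid, ivs in synthetic.read_truth_tsv(annotations).items()
        }
    else:
        ann_map = {r.id: topology.call_tms_seq(r.seq, config.caller()).intervals for r in records}
    usable = [r for r in records if len(ann_map.get(r.id, [])) > split_after_tms]
    if not usable:
        raise ValueError("no record has more TMSs than the split index")
    report = repeat_scan.repeat_test(
        usable,
        ann_map,
        split_after_tms,
        config.scheme(),
        config.flank,
        config.top_k,
        config.n_shuffles,
        config.criteria(),
        _stage_seed(config, "repeatscan"),
    )
    _write_tsv(pd.DataFrame(report.to_rows()), outdir / "scan.tsv", config)
    with open(outdir / "alignments.txt", "w") as fh:
        fh.write(_header(config))
        for pair in report.passing:
            fh.write(f"## {pair.bundle_a.label} vs {pair.bundle_b.label} z={pair.z:.1f}\n")
            fh.write(
                pairwise.format_alignment(
                    pair.alignment,
                    pair.bundle_a.label,
                    pair.bundle_b.label,
                    config.scheme(),
                    pair.bundle_a.tms_local,
                    pair.bundle_b.tms_local,
                )
            )
            fh.write("\n")
    return report


def run_network(
    config: RunConfig,
    outdir: Path,
    evidence: Path | None = None,
    use_bundled_table: bool = False,
) -> dict:
    """Build the homology network and report superfamily components."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if use_bundled_table:
        edges = superfamily.table1_fixture()
    elif evidence:
        df = pd.read_csv(evidence, sep="\t", comment="#")
        edges = [
            superfamily.EvidenceEdge(
                str(r.node_a), str(r.node_b), float(r.z),
                passes=float(r.z) >= config.z_min,
            )
            for r in df.itertuples()
        ]
    else:
        edges = []
    net = superfamily.build_network(edges)
    result = {}
    for z_min in (0.0, config.z_min):
        comps = superfamily.components(net, z_min)
        result[z_min] = comps
        with open(outdir / f"components_z{z_min:g}.tsv", "w") as fh:
            fh.write(_header(config))
            fh.write("component\tsize\tmembers\n")
            for i, comp in enumerate(comps, start=1):
                fh.write(f"{i}\t{len(comp)}\t{','.join(sorted(comp))}\n")
    for fmt, name in (("sif", "network.sif"), ("graphml", "network.graphml"),
                      ("tsv-edgelist", "network.tsv")):
        (outdir / name).write_text(superfamily.export_network(net, fmt))
    return result


def run_ancestor(
    config: RunConfig,
    fasta: Path,
    split_after_tms: int,
    outdir: Path,
    annotations: Path | None = None,
) -> dict:
    """Reconstruct half-roots and compare ancestral vs extant z."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = synthetic.read_fasta(fasta)
    if annotations:
        ann_map = synthetic.read_truth_tsv(annotations)
    else:
        ann_map = {r.id: topology.call_tms_seq(r.seq, config.caller()).intervals for r in records}
    records = [r for r in records if len(ann_map.get(r.id, [])) > split_after_tms]
    out = ancestral.ancestral_repeat_compare(
        records,
        ann_map,
        split_after_tms,
        config.scheme(),
        n_shuffles=config.n_shuffles,
        seed=_stage_seed(config, "ancestor"),
    )
    with open(outdir / "roots.fasta", "w") as fh:
        fh.write(f">root_half1\n{out['root_1']}\n>root_half2\n{out['root_2']}\n")
    rows = [("ancestral", out["ancestral"].z, out["ancestral"].quality)]
    rows += [(f"extant_{i}", s.z, s.quality) for i, s in enumerate(out["extant"])]
    _write_tsv(pd.DataFrame(rows, columns=["pair", "z", "Q"]), outdir / "ancestral_z.tsv", config)
    return out


def run_superpose(
    config: RunConfig,
    pdb: Path,
    chain_a: str,
    range_a: tuple[int, int],
    chain_b: str,
    range_b: tuple[int, int],
    outdir: Path,
    cutoff: float = 2.0,
) -> superpose.SuperpositionResult:
    """Alignment-free positional pruned superposition of two chain ranges."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    text = Path(pdb).read_text()
    seg_a = superpose.read_ca(text, chain_a, range_a)
    seg_b = superpose.read_ca(text, chain_b, range_b)
    n = min(len(seg_a), len(seg_b))
    pairing = [(i, i) for i in range(n)]
    result = superpose.iterative_prune(seg_a, seg_b, pairing, cutoff)
    with open(outdir / "superposition.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("metric\tvalue\n")
        fh.write(f"rmsd\t{result.rmsd:.3f}\n")
        fh.write(f"retained_pairs\t{len(result.retained_pairs)}\n")
        fh.write(f"iterations\t{result.iterations}\n")
    transformed = superpose.CoordinateSegment(
        seg_b.chain, seg_b.residue_numbers, result.transform(seg_b.coords)
    )
    (outdir / "transformed.pdb").write_text(superpose.write_ca_pdb(transformed))
    return result
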
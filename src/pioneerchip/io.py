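"""Readers/writers for the external formats and the pipeline orchestrator.

Formats: bedGraph (probe and conservation tracks), fixedStep WIG
(conservation), BED6 (regions, 0-based half-open), FASTA (sequences),
JASPAR/TRANSFAC matrices (see motifs module), TSV tables, JSON config and
run manifest. All writes are atomic (write to a temporary file in the
target directory, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import conservation as cons_mod
from . import ihc as ihc_mod
from . import motifs as motifs_mod
from . import peaks as peaks_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write-then-rename so readers never observe a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# bedGraph / WIG
# ---------------------------------------------------------------------------

def read_bedgraph(path, allow_overlap: bool = False) -> dict[str, peaks_mod.ProbeTrack]:
    """Parse a 4-column bedGraph into per-chromosome probe tracks.

    Track/browser/comment lines are ignored. Unsorted input is sorted with
    a warning; overlapping intervals on a chromosome are an error naming
    the offending line unless ``allow_overlap`` is set (tiling probes, 50
    nt every 24 bp, overlap by construction — starts must still be
    strictly increasing).
    """
    records: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts[:4]
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            records.setdefault(chrom, []).append((start, end, value, lineno))
    tracks = {}
    for chrom, rows in records.items():
        if any(rows[i][0] > rows[i + 1][0] for i in range(len(rows) - 1)):
            logger.warning("%s: %s intervals unsorted; sorting", path, chrom)
            rows = sorted(rows)
        for i in range(len(rows) - 1):
            if rows[i + 1][0] <= rows[i][0]:
                raise ValueError(f"{path}:{rows[i + 1][3]}: duplicate interval start")
            if not allow_overlap and rows[i + 1][0] < rows[i][1]:
                raise ValueError(f"{path}:{rows[i + 1][3]}: interval overlaps the previous one")
        arr = np.array([(r[0], r[1], r[2]) for r in rows], dtype=np.float64)
        tracks[chrom] = peaks_mod.ProbeTrack(chrom, arr[:, 0].astype(np.int64),
                                             arr[:, 1].astype(np.int64), arr[:, 2])
    return tracks


def write_bedgraph(track: peaks_mod.ProbeTrack, path, name: str = "track") -> None:
    with atomic_write(path) as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_conservation_bedgraph(path) -> cons_mod.ConservationTrack:
    """Per-base conservation from a bedGraph; gaps stay missing (NaN)."""
    tracks = read_bedgraph(path)
    scores = {}
    for chrom, t in tracks.items():
        arr = np.full(int(t.ends.max()), np.nan)
        for s, e, v in zip(t.starts, t.ends, t.values):
            arr[s:e] = v
        scores[chrom] = arr
    return cons_mod.ConservationTrack(scores)


def read_wig(path) -> cons_mod.ConservationTrack:
    """fixedStep WIG reader (step/span default 1)."""
    chrom, pos, step, span = None, 0, 1, 1
    arrays: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                arrays.setdefault(chrom, {})
                continue
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: data before any fixedStep header")
            try:
                value = float(line)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from None
            for off in range(span):
                arrays[chrom][pos + off] = value
            pos += step
    out = {}
    for chrom, mapping in arrays.items():
        arr = np.full(max(mapping) + 1, np.nan)
        idx = np.fromiter(mapping.keys(), dtype=np.int64)
        arr[idx] = np.fromiter(mapping.values(), dtype=np.float64)
        out[chrom] = arr
    return cons_mod.ConservationTrack(out)


def write_conservation_wig(track: cons_mod.ConservationTrack, path,
                           name: str = "conservation") -> None:
    with atomic_write(path) as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom, arr in track.scores.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.writelines(f"{v:.4f}\n" for v in arr)


# ---------------------------------------------------------------------------
# BED6 regions
# ---------------------------------------------------------------------------

def write_bed(regions, path) -> None:
    """BED6: name = region id, score = -10*log10(p) capped at 1000."""
    with atomic_write(path) as fh:
        for i, r in enumerate(regions, start=1):
            score = min(1000, int(round(-10.0 * math.log10(max(r.p_value, 1e-300)))))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i:04d}\t{score}\t.\n")


def read_bed(path) -> list[peaks_mod.ChIPRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                score = float(parts[4]) if len(parts) >= 5 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            p = 10.0 ** (-score / 10.0)
            regions.append(peaks_mod.ChIPRegion(parts[0], start, end,
                                                best_t=float("nan"), p_value=min(1.0, p)))
    return regions


def write_regions_tsv(regions, path) -> None:
    df = pd.DataFrame([{"chrom": r.chrom, "start": r.start, "end": r.end,
                        "best_t": r.best_t, "p_value": r.p_value,
                        "sources": ",".join(sorted(r.sources))} for r in regions])
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


def write_fasta(records, path) -> None:
    from Bio import SeqIO
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


def write_tsv(df: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Single-file JSON configuration; unknown keys are rejected.

    Defaults are the published operating point: w=400, g=100, alpha=1e-4,
    activity cutoff 1e-4 of the albumin analog, 5-kb proximal rule,
    2-fold qPCR positivity.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    w: int = 400
    g: int = 100
    alpha: float = 1e-4
    trim_fraction: float = 0.10
    min_probes: int = 5
    activity_cutoff: float = 1e-4
    proximal_cutoff: int = 5000
    positivity_fold: float = 2.0
    conservation_elevation: float = 0.4
    conservation_half_width: int = 1000
    genome_length: int = 2_400_000
    n_decoy_motifs: int = 17
    motif_grid_size: int = 50

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        write_json(dataclasses.asdict(self), path)

    def peak_params(self) -> peaks_mod.PeakCallParams:
        return peaks_mod.PeakCallParams(w=self.w, g=self.g, alpha=self.alpha,
                                        trim_fraction=self.trim_fraction,
                                        min_probes=self.min_probes)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Synthetic end-to-end run: simulate -> call peaks -> locate elements ->
    2-D motif enrichment -> activity annotation -> conservation -> manifest.

    Each stage writes its outputs under ``config.outdir`` and its counts
    into the returned JSON manifest; a stage failure aborts with the stage
    name while earlier outputs stay on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": dataclasses.asdict(config),
                      "seed": config.seed, "stages": {}, "checksums": {}}
    stage = "simulate"
    try:
        sim = sim_mod.default_config(seed=config.seed)
        sim.genome_length = config.genome_length
        n_loci = sim.expression.n_active + sim.expression.n_silent
        spacing = sim.genome_length // (n_loci + 1)
        sim.spikes = [sim_mod.SpikeSpec(center=(i + 1) * spacing, half_width=200,
                                        height=3.0 * sim.noise_sd)
                      for i in range(n_loci)]
        tracks = {ch: sim_mod.simulate_probe_track(sim, ch) for ch in peaks_mod.CHANNELS}
        for ch, tr in tracks.items():
            write_bedgraph(tr, outdir / f"{ch}.bedgraph", name=ch)
        expr = sim_mod.simulate_expression(sim.expression, seed=sim.seed)
        write_tsv(expr.drop(columns=["true_class"]), outdir / "expression.tsv")
        annotation = sim_mod.simulate_annotation(sim, list(expr["gene"]))
        write_tsv(annotation, outdir / "annotation.tsv")
        ihc_counts = sim_mod.simulate_ihc_counts(sim.ihc, seed=sim.seed)
        write_tsv(ihc_counts, outdir / "ihc_counts.tsv")
        manifest["stages"][stage] = {"n_probes": len(tracks[peaks_mod.CHIP_VS_IGG]),
                                     "n_spiked_loci": len(sim.spikes),
                                     "n_genes": len(expr)}

        stage = "callpeaks"
        params = config.peak_params()
        regions = peaks_mod.call_regions(
            {ch: tracks[ch] for ch in peaks_mod.CHIP_CHANNELS}, params)
        fdr = peaks_mod.estimate_fdr_from_control(
            len(regions), tracks[peaks_mod.IGG_VS_INPUT], params)
        write_bed(regions, outdir / "regions.bed")
        write_regions_tsv(regions, outdir / "regions.tsv")
        manifest["stages"][stage] = {"n_regions": len(regions),
                                     "fdr": fdr.fdr if fdr.defined else None,
                                     "n_control_regions": fdr.n_control_regions}

        stage = "activity"
        labels = activity_mod.classify_activity(expr, sim.expression.albumin_gene,
                                                cutoff=config.activity_cutoff)
        assignments = activity_mod.nearest_tss_assignment(regions, annotation)
        table, odds = activity_mod.proximal_activity_table(
            assignments, labels, proximal_cutoff=config.proximal_cutoff)
        write_tsv(pd.DataFrame({"gene": labels.index, "label": labels.to_numpy()}),
                  outdir / "activity_labels.tsv")
        write_tsv(assignments, outdir / "tss_assignments.tsv")
        manifest["stages"][stage] = {
            "n_active": int((labels == "active").sum()),
            "n_silent": int((labels == "silent").sum()),
            "proximal_active": int(table.loc["proximal", "active"]),
            "odds_ratio": odds}

        stage = "sequences"
        region_labels = [str(labels.get(g, "active"))
                         for g in assignments.set_index("region_index")["gene"]
                         .reindex(range(len(regions)))]
        records, truth = sim_mod.simulate_sequences(sim, regions, region_labels)
        write_fasta(records, outdir / "regions.fasta")
        write_tsv(truth, outdir / "motif_truth.tsv")
        manifest["stages"][stage] = {"n_sequences": len(records),
                                     "n_embedded_motifs": len(truth)}

        stage = "enrich2d"
        seqs = [str(r.seq) for r in records]
        library = [sim.motif_embed.primary_pwm] + \
                  [p for p, _ in sim.motif_embed.co_pwms_active] + \
                  [p for p, _ in sim.motif_embed.co_pwms_silent] + \
                  motifs_mod.decoy_library(config.n_decoy_motifs, seed=config.seed)
        region_set = motifs_mod.RegionSequenceSet.from_element_centered(
            [r.id for r in records], seqs, region_labels)
        enrich = motifs_mod.two_dimensional_significance(
            region_set, library, grid_size=config.motif_grid_size)
        write_tsv(enrich, outdir / "enrichment.tsv")
        write_tsv(enrich[["motif", "neglog10_p_dim1", "neglog10_p_dim2"]],
                  outdir / "enrichment_axes.tsv")
        manifest["stages"][stage] = {"n_motifs": len(library),
                                     "top_dim1": str(enrich.sort_values("p_dim1")["motif"].iloc[0])}

        stage = "conservation"
        bound = [(r.chrom, r.midpoint) for r in regions]
        spike_spans = {(s.start, s.end) for s in sim.spikes}
        rng = sim_mod.stream_rng(config.seed, "unbound_sites")
        unbound = []
        while len(unbound) < max(100, 2 * len(bound)):
            pos = int(rng.integers(config.conservation_half_width,
                                   sim.genome_length - config.conservation_half_width))
            if all(not (s - 500 <= pos < e + 500) for s, e in spike_spans):
                unbound.append((sim.chrom, pos))
        cons_track = sim_mod.simulate_conservation(
            sim, regions, elevation=config.conservation_elevation)
        comparison = cons_mod.compare_site_sets(
            cons_track, bound, unbound, half_width=config.conservation_half_width,
            seed=config.seed)
        manifest["stages"][stage] = {
            "bound_grand_mean": comparison["bound"].grand_mean,
            "unbound_grand_mean": comparison["unbound"].grand_mean,
            "difference": comparison["difference"],
            "bootstrap_ci": list(comparison["bootstrap_ci"])}

        stage = "ihc"
        summaries = ihc_mod.summaries_from_counts(ihc_counts)
        report = ihc_mod.stage_contrast_report(summaries, "normal_GEJ")
        write_tsv(report, outdir / "ihc_contrasts.tsv")
        manifest["stages"][stage] = {
            "contrasts": {f"{row.reference}_vs_{row.stage}": row.p
                          for row in report.itertuples()}}
    except Exception as exc:
        manifest["failed_stage"] = stage
        write_json(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][f.name] = sha256_file(f)
    write_json(manifest, outdir / "manifest.json")
    return manifest
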
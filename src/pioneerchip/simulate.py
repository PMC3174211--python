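"""Synthetic data with the statistical structure the analysis assumes.

Emulates a tiled-array ChIP-chip experiment on a toy genome: 50-nt probes
every 24 bp carrying symmetric Gaussian log-ratio noise plus rectangular
enrichment spikes at chosen loci; locus sequences with PWM-sampled motif
instances placed near peak centers (different co-motif composition for
active vs silent loci); a conservation track elevated at bound sites;
qPCR Ct tables spanning several orders of magnitude of relative
expression; and per-sample nucleus counts for the staging statistics.

Every draw flows from one integer seed through a single stream-splitting
rule: component X uses ``default_rng(SeedSequence(seed, spawn_key=(crc32(X),)))``,
so components are independent and individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import PositionWeightMatrix, foxa_pwm, hnf4_pwm, reverse_complement, rfx_pwm
from .peaks import CHANNELS, CHIP_VS_IGG, CHIP_VS_INPUT, ChIPRegion, ProbeTrack

SEQ_LEN = 1000          # simulated locus sequence length
FOREGROUND_LEN = 500    # central region receiving co-motifs


def stream_rng(seed: int, label: str) -> np.random.Generator:
    """The package-wide stream-splitting rule (one child stream per label)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SpikeSpec:
    """A rectangular enrichment spike: constant added log-ratio over
    [center - half_width, center + half_width) in the listed channels."""

    center: int
    half_width: int
    height: float
    channels: frozenset = frozenset({CHIP_VS_IGG, CHIP_VS_INPUT})

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        self.channels = frozenset(self.channels)
        unknown = self.channels - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {unknown}")

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width


@dataclass
class MotifEmbedSpec:
    """What motif content the locus sequences carry."""

    primary_pwm: PositionWeightMatrix = field(default_factory=foxa_pwm)
    co_pwms_active: list = field(default_factory=lambda: [(hnf4_pwm(), 0.8)])
    co_pwms_silent: list = field(default_factory=lambda: [(rfx_pwm(), 0.8)])
    embed_window: int = 50
    background_base_composition: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.background_base_composition = np.asarray(self.background_base_composition, float)
        if not np.isclose(self.background_base_composition.sum(), 1.0):
            raise ValueError("background base composition must sum to 1")
        for _, p in list(self.co_pwms_active) + list(self.co_pwms_silent):
            if not 0.0 <= p <= 1.0:
                raise ValueError("embed probabilities must lie in [0, 1]")


@dataclass
class ExpressionSpec:
    """Relative-expression structure of the qPCR table.

    Ranges are relative to the albumin-analog gene (fixed at 1.0); the
    silent range must sit entirely below the 1e-4 classification cutoff
    and the active range entirely at or above it.
    """

    n_active: int = 56
    n_silent: int = 30
    active_rel_range: tuple = (1e-4, 10.0)
    silent_rel_range: tuple = (1e-9, 1e-5)
    reference_gene: str = "Hprt"
    albumin_gene: str = "Alb1"
    ct_reference: float = 20.0

    def __post_init__(self) -> None:
        if self.silent_rel_range[1] >= 1e-4:
            raise ValueError("silent range must lie entirely below 1e-4 of albumin")
        if self.active_rel_range[0] < 1e-4:
            raise ValueError("active range must lie entirely at/above 1e-4 of albumin")
        if self.n_active < 1 or self.n_silent < 0:
            raise ValueError("need at least one active gene (the albumin analog)")


@dataclass
class IhcStageSpec:
    n_samples: int
    mean_fraction_positive: float
    sd_fraction: float
    nuclei_low: int = 300
    nuclei_high: int = 600

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_fraction_positive <= 1.0:
            raise ValueError("mean_fraction_positive must lie in [0, 1]")
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")
        if self.nuclei_low <= 0 or self.nuclei_high < self.nuclei_low:
            raise ValueError("nucleus count bounds must be positive and ordered")


# Published staging summaries: per-stage n, mean % positive nuclei and SEM;
# the generator's per-sample SD is SEM * sqrt(n).
TABLE1_STAGES: dict[str, IhcStageSpec] = {
    "normal_GEJ": IhcStageSpec(5, 0.616, 0.033 * np.sqrt(5)),
    "barretts": IhcStageSpec(11, 0.422, 0.076 * np.sqrt(11)),
    "dysplastic_barretts": IhcStageSpec(6, 0.048, 0.020 * np.sqrt(6)),
    "adenocarcinoma": IhcStageSpec(20, 0.033, 0.020 * np.sqrt(20)),
}


@dataclass
class IhcSpec:
    stages: dict = field(default_factory=lambda: dict(TABLE1_STAGES))


@dataclass
class SimulationConfig:
    genome_length: int = 2_400_000
    chrom: str = "chr1"
    probe_length: int = 50
    probe_spacing: int = 24
    noise_sd: float = 0.5
    seed: int = 0
    spikes: list = field(default_factory=list)
    motif_embed: MotifEmbedSpec = field(default_factory=MotifEmbedSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    ihc: IhcSpec = field(default_factory=IhcSpec)

    def __post_init__(self) -> None:
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.genome_length < self.probe_length:
            raise ValueError("genome shorter than one probe")


def default_config(seed: int = 0) -> SimulationConfig:
    """The study-condition default: 86 spiked loci (one per assayed gene,
    56 active + 30 silent) of height 3x the probe noise SD on a 2.4-Mb
    genome tiled at 50-nt probes every 24 bp."""
    cfg = SimulationConfig(seed=seed)
    n_loci = cfg.expression.n_active + cfg.expression.n_silent
    spacing = cfg.genome_length // (n_loci + 1)
    cfg.spikes = [SpikeSpec(center=(i + 1) * spacing, half_width=200,
                            height=3.0 * cfg.noise_sd) for i in range(n_loci)]
    return cfg


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------

def simulate_probe_track(config: SimulationConfig, comparison: str) -> ProbeTrack:
    """One log-ratio measurement per probe for one hybridization comparison.

    value = Normal(0, noise_sd) + sum of heights of spikes whose span
    covers the probe midpoint and whose channel set includes the
    comparison.
    """
    if comparison not in CHANNELS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if config.genome_length < config.probe_length:
        raise ValueError("genome shorter than one probe")
    starts = np.arange(0, config.genome_length - config.probe_length + 1,
                       config.probe_spacing, dtype=np.int64)
    ends = starts + config.probe_length
    mids = (starts + ends) // 2
    rng = stream_rng(config.seed, f"probe_track:{comparison}")
    values = rng.normal(0.0, config.noise_sd, size=len(starts))
    for spike in config.spikes:
        if comparison in spike.channels and spike.height != 0.0:
            inside = (mids >= spike.start) & (mids < spike.end)
            values[inside] += spike.height
    return ProbeTrack(chrom=config.chrom, starts=starts, ends=ends, values=values)


# ---------------------------------------------------------------------------
# Locus sequences with embedded motifs
# ---------------------------------------------------------------------------

def _sample_instance(pwm: PositionWeightMatrix, rng: np.random.Generator) -> str:
    probs = pwm.probabilities()
    return "".join("ACGT"[rng.choice(4, p=probs[:, j])] for j in range(pwm.width))


def _place(seq: list, instance: str, start: int, occupied: list) -> bool:
    span = (start, start + len(instance))
    for s, e in occupied:
        if span[0] < e and s < span[1]:
            return False
    seq[span[0]:span[1]] = list(instance)
    occupied.append(span)
    return True


def simulate_sequences(config: SimulationConfig, regions: list[ChIPRegion],
                       activity_labels: list[str]) -> tuple[list, pd.DataFrame]:
    """A 1000-nt sequence per region, centered on the region center.

    Background bases are i.i.d. from the configured composition. One
    primary-motif instance is placed within ``embed_window`` of the
    center; co-motifs are sampled per activity label (Bernoulli embed
    probability each) and placed uniformly within the central 500 nt.
    Returns Biopython SeqRecords plus a truth table of placements.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    spec = config.motif_embed
    if spec.embed_window > SEQ_LEN // 2:
        raise ValueError("embed_window larger than half the sequence length")
    if len(regions) != len(activity_labels):
        raise ValueError("one activity label per region is required")
    rng = stream_rng(config.seed, "sequences")
    records, truth = [], []
    center = SEQ_LEN // 2
    lo_a, hi_a = center - FOREGROUND_LEN // 2, center + FOREGROUND_LEN // 2
    for region, label in zip(regions, activity_labels):
        if label not in ("active", "silent"):
            raise ValueError(f"unknown activity label {label!r}")
        name = f"{region.chrom}:{region.start}-{region.end}"
        seq = list(rng.choice(list("ACGT"), size=SEQ_LEN,
                              p=spec.background_base_composition))
        occupied: list = []

        def embed(pwm, lo, hi, role):
            instance = _sample_instance(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = instance if strand == "+" else reverse_complement(instance)
            for _ in range(100):
                start = int(rng.integers(lo, hi - pwm.width + 1))
                if _place(seq, placed, start, occupied):
                    truth.append({"region": name, "motif": pwm.name, "role": role,
                                  "start": start, "strand": strand, "label": label})
                    return
            raise RuntimeError("could not place a motif instance without overlap")

        embed(spec.primary_pwm,
              max(0, center - spec.embed_window),
              min(SEQ_LEN, center + spec.embed_window + spec.primary_pwm.width),
              "primary")
        co_pwms = spec.co_pwms_active if label == "active" else spec.co_pwms_silent
        for pwm, prob in co_pwms:
            if rng.random() < prob:
                embed(pwm, lo_a, hi_a, "co")
        records.append(SeqRecord(Seq("".join(seq)), id=name, description=label))
    return records, pd.DataFrame(truth, columns=["region", "motif", "role",
                                                 "start", "strand", "label"])


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------

def simulate_conservation(config: SimulationConfig, bound_regions: list,
                          unbound_regions: list | None = None,
                          elevation: float = 0.4,
                          baseline_beta: tuple = (1.0, 9.0)):
    """Per-base conservation scores in [0, 1].

    Baseline scores are Beta-distributed (defaults give a genome-typical
    mean of 0.1); bases inside bound regions are raised by ``elevation``
    and clipped at 1. ``unbound_regions`` is accepted for symmetry with
    the downstream comparison but receives no elevation.
    """
    from .conservation import ConservationTrack

    if elevation < 0:
        raise ValueError("elevation must be >= 0")
    rng = stream_rng(config.seed, "conservation")
    scores = rng.beta(*baseline_beta, size=config.genome_length)
    for region in bound_regions:
        start, end = max(0, int(region.start)), min(config.genome_length, int(region.end))
        scores[start:end] = np.minimum(scores[start:end] + elevation, 1.0)
    return ConservationTrack({config.chrom: scores})


# ---------------------------------------------------------------------------
# Expression (delta-Ct) table
# ---------------------------------------------------------------------------

def simulate_expression(spec: ExpressionSpec, seed: int = 0) -> pd.DataFrame:
    """Per-gene Ct table whose delta-Ct relative expression reproduces the
    target values exactly: Ct_gene = Ct_ref - log2(relative expression).

    The albumin analog is one of the active genes (relative expression
    1.0); the reference gene enters as the per-row ct_ref column.
    """
    rng = stream_rng(seed, "expression")

    def log_uniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    genes, rel, cls = [spec.albumin_gene], [1.0], ["active"]
    for v in log_uniform(*spec.active_rel_range, spec.n_active - 1):
        genes.append(f"act{len(genes):03d}")
        rel.append(float(v))
        cls.append("active")
    for v in log_uniform(*spec.silent_rel_range, spec.n_silent):
        genes.append(f"sil{len(genes):03d}")
        rel.append(float(v))
        cls.append("silent")
    rel_arr = np.array(rel)
    ct_gene = spec.ct_reference - np.log2(rel_arr)
    return pd.DataFrame({"gene": genes, "ct_gene": ct_gene,
                         "ref_gene": spec.reference_gene,
                         "ct_ref": spec.ct_reference,
                         "true_class": cls})


# ---------------------------------------------------------------------------
# IHC nucleus counts
# ---------------------------------------------------------------------------

def simulate_ihc_counts(spec: IhcSpec, seed: int = 0) -> pd.DataFrame:
    """Per-sample nucleus counts per disease stage.

    total ~ UniformInt[nuclei_low, nuclei_high]; a per-sample staining
    propensity is drawn Normal(mean_fraction_positive, sd_fraction),
    clipped to [0, 1]; stained ~ Binomial(total, propensity).
    """
    rng = stream_rng(seed, "ihc")
    rows = []
    for stage, st in spec.stages.items():
        for i in range(st.n_samples):
            total = int(rng.integers(st.nuclei_low, st.nuclei_high + 1))
            p_s = float(np.clip(rng.normal(st.mean_fraction_positive, st.sd_fraction), 0.0, 1.0))
            stained = int(rng.binomial(total, p_s))
            rows.append({"sample": f"{stage}_{i + 1:02d}", "stage": stage,
                         "total_nuclei": total, "stained_nuclei": stained})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene annotation linked to the spiked loci
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, genes: list[str],
                        tss_offset_range: tuple = (-2000, 2000)) -> pd.DataFrame:
    """One gene per spiked locus: TSS near the spike center (uniform offset),
    random strand. Requires one gene name per spike."""
    if len(genes) != len(config.spikes):
        raise ValueError("need exactly one gene name per spiked locus")
    rng = stream_rng(config.seed, "annotation")
    rows = []
    for gene, spike in zip(genes, config.spikes):
        offset = int(rng.integers(*tss_offset_range))
        rows.append({"gene": gene, "chrom": config.chrom,
                     "tss": max(0, spike.center + offset),
                     "strand": "+" if rng.random() < 0.5 else "-"})
    return pd.DataFrame(rows)
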
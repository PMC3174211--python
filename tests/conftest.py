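import numpy as np
import pytest

from pioneerchip import peaks as pk
from pioneerchip import simulate as sim


@pytest.fixture
def small_noise_config():
    """Spike-free track config small enough for brute-force oracles."""
    return sim.SimulationConfig(genome_length=20_000, seed=7, spikes=[])


def make_track(values, spacing=24, probe_len=50, chrom="chr1"):
    """Probe track with explicit values on a regular grid."""
    values = np.asarray(values, dtype=np.float64)
    starts = np.arange(len(values)) * spacing
    return pk.ProbeTrack(chrom, starts, starts + probe_len, values)


def brute_force_window_scores(track, params):
    """Independent per-window recomputation of the T statistic."""
    mids = (track.starts + track.ends) // 2
    half = params.w // 2
    out = []
    for m in mids:
        inside = (mids >= m - half) & (mids < m + half)
        x = np.sort(track.values[inside])
        n = len(x)
        if n < params.min_probes:
            continue
        k = int(np.floor(params.trim_fraction * n))
        if 2 * k >= n:
            k = (n - 1) // 2
        core = x[k:n - k] if k else x
        out.append((int(m), n, np.sqrt(n) * core.mean()))
    return out
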
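#!/usr/bin/env python
"""Conservation profiles around bound vs unbound sites.

Simulates a per-base conservation track with a 0.4 elevation inside the
called regions, extracts 2-kb windows around region midpoints and around
matched random unbound positions, and compares the mean profiles with a
site-level bootstrap interval.
"""

from pathlib import Path

import pandas as pd

from pioneerchip import conservation as cons
from pioneerchip import io as io_mod
from pioneerchip import simulate as sim

OUT = Path("results")
SEED = 0
HALF_WIDTH = 1000


def main() -> None:
    regions = io_mod.read_bed(OUT / "regions.bed")
    cfg = sim.default_config(seed=SEED)
    track = sim.simulate_conservation(cfg, regions, elevation=0.4)

    bound = [(r.chrom, r.midpoint) for r in regions]
    spans = [(r.start, r.end) for r in regions]
    rng = sim.stream_rng(SEED, "unbound_sites")
    unbound = []
    while len(unbound) < 2 * len(bound):
        pos = int(rng.integers(HALF_WIDTH, cfg.genome_length - HALF_WIDTH))
        if all(not (s - 500 <= pos < e + 500) for s, e in spans):
            unbound.append((cfg.chrom, pos))

    res = cons.compare_site_sets(track, bound, unbound, half_width=HALF_WIDTH,
                                 seed=SEED)
    profile = pd.DataFrame({"offset": res["bound"].offsets,
                            "bound_mean": res["bound"].mean,
                            "unbound_mean": res["unbound"].mean})
    io_mod.write_tsv(profile, OUT / "conservation_profile.tsv")
    lo, hi = res["bootstrap_ci"]
    print(f"{len(bound)} bound vs {len(unbound)} unbound sites, 2-kb windows")
    print(f"grand means: bound {res['bound'].grand_mean:.3f}, "
          f"unbound {res['unbound'].grand_mean:.3f}")
    print(f"difference {res['difference']:.3f} (bootstrap 95% CI "
          f"[{lo:.3f}, {hi:.3f}]; regions are narrower than the 2-kb window, "
          f"so the grand-mean difference understates the 0.4 elevation)")
    print(f"outputs: {OUT/'conservation_profile.tsv'}")


if __name__ == "__main__":
    main()
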
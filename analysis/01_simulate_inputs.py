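#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the three competitive-hybridization probe tracks (86 spiked loci,
one per assayed gene, on a 2.4-Mb tiled genome), the delta-Ct expression
table (56 active / 30 silent by construction), the gene annotation, and
the per-sample nucleus counts, all under results/data/.
"""

from pathlib import Path

import pandas as pd

from pioneerchip import io as io_mod
from pioneerchip import peaks as pk
from pioneerchip import simulate as sim

OUT = Path("results/data")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sim.default_config(seed=SEED)
    for ch in pk.CHANNELS:
        track = sim.simulate_probe_track(cfg, ch)
        io_mod.write_bedgraph(track, OUT / f"{ch}.bedgraph", name=ch)
        print(f"{ch}: {len(track)} probes -> {OUT / f'{ch}.bedgraph'}")

    expr = sim.simulate_expression(cfg.expression, seed=SEED)
    io_mod.write_tsv(expr.drop(columns=["true_class"]), OUT / "expression.tsv")
    annotation = sim.simulate_annotation(cfg, list(expr["gene"]))
    io_mod.write_tsv(annotation, OUT / "annotation.tsv")
    counts = sim.simulate_ihc_counts(cfg.ihc, seed=SEED)
    io_mod.write_tsv(counts, OUT / "ihc_counts.tsv")
    truth = pd.DataFrame([{"chrom": cfg.chrom, "start": s.start, "end": s.end,
                           "height": s.height} for s in cfg.spikes])
    io_mod.write_tsv(truth, OUT / "spike_truth.tsv")
    print(f"{len(cfg.spikes)} spiked loci, {len(expr)} genes, "
          f"{len(counts)} IHC samples -> {OUT}")


if __name__ == "__main__":
    main()
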
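"""The ping-pong signature: 5'-overlap histogram of opposite-strand pairs.

Secondary piRNA biogenesis leaves an excess of plus/minus pairs whose 5'
ends overlap by exactly 10 nt, with U at position 1 of one mate and A at
position 10 of the other. We compare a positive control (50% partner rate)
with a negative control (no partners).
"""
import numpy as np

from pirnakit.annotate import align_exact
from pirnakit.io import Tag
from pirnakit.pingpong import overlap_histogram, partner_base_freq
from pirnakit.synth import SimConfig, simulate_genome


def signature(rate: float):
    cfg = SimConfig(seed=5, n_chroms=2, chrom_length=500_000, n_clusters=12,
                    cluster_span=(1500, 3000), tags_per_cluster=(40, 80),
                    pingpong_rate=rate, background={})
    ds = simulate_genome(cfg)
    tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in ds.tag_truth.iterrows()]
    alns_by_tag, _ = align_exact(tags, ds.genome)
    alns = [a for alns in alns_by_tag.values() for a in alns]
    hist = overlap_histogram(alns, weight="unique")
    return ds, tags, hist


for rate in (0.5, 0.0):
    ds, tags, hist = signature(rate)
    top = int(np.argmax(hist.weights) + 1)
    print(f"partner rate {rate}: top overlap bin = {top} nt, z10 = {hist.z10:.2f}")
    if rate == 0.5:
        freq = partner_base_freq(hist, {t.tag_id: t.sequence for t in tags})
        print(f"  bin-10 partners: T at position 1 = {freq.loc[1, 'T']:.2f}, "
              f"A at position 10 = {freq.loc[10, 'A']:.2f}")
# A z10 above ~3 marks a clear ping-pong peak; near 0 means no enrichment
# of the 10-nt overlap over the other overlap lengths.
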
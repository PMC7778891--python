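"""Quantitative value enrichment: are in-term gene values non-random?

Gene-level values (e.g. expression changes) are compared between genes
carrying a term and all others with a two-sided Mann-Whitney U test.  One
term's genes are shifted upward; a second term is null.
"""

import numpy as np

from phylograft import run_value_enrichment

rng = np.random.default_rng(0)
values = {f"BG{i}": float(v) for i, v in enumerate(rng.normal(size=400))}
values.update({f"UP{i}": float(rng.normal(loc=1.5)) for i in range(40)})

term_map = {
    "SHIFTED": {f"UP{i}" for i in range(40)},
    "RANDOM": set(list(values)[::7]),
}
rows, skipped = run_value_enrichment(values, term_map, correction="fdr_bh")
for r in rows:
    print(f"{r.term_id:8s} n_in={r.n_in:3d}  U={r.u_statistic:8.1f}  "
          f"{r.direction:5s}  p_adj={r.p_adjusted:.3g}")
# U above n_in*n_out/2 means in-term values tend to be higher ("over").
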
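"""Absolute-abundance community structure: distances, PCoA, PERMANOVA.

Scales amplicon proportions by qPCR loads, then asks: does gut
colonization structure the communities (yes, strongly), and do pesticides
shift communities within the colonized stratum (no) or within the
depleted stratum (weakly, with heterogeneous dispersion)?
"""

import warnings

from beegut import absolute_abundance, asv_filtering, community_ecology as ce, qpcr
from beegut.synthetic_data import SimulationConfig, simulate_experiment

warnings.filterwarnings("ignore")

ds = simulate_experiment(SimulationConfig(seed=1))
loads, _ = qpcr.quantify(ds.cq_table, ds.dilution_series)
filtered, _ = asv_filtering.taxonomy_filter(ds.asv_counts, ds.taxonomy)
calls = asv_filtering.identify_contaminants(
    filtered, ds.metadata["is_blank"], loads["normalized_16S"],
    strata=ds.metadata.loc[~ds.metadata["is_blank"], "colonization"])
counts = asv_filtering.remove_contaminants(filtered, calls, ds.metadata["is_blank"])
table = absolute_abundance.build_absolute_table(counts, loads["normalized_16S"])
meta = ds.metadata.loc[table.index]

bc = ce.bray_curtis(table)
ord_res = ce.pcoa(bc)
print("PCoA axis 1/2 explain "
      f"{100 * ord_res.proportion_explained[0]:.1f}% / "
      f"{100 * ord_res.proportion_explained[1]:.1f}% of positive inertia")

perm = ce.permanova(bc, meta["colonization"], n_permutations=999, seed=1)
print(f"colonization: pseudo-F = {perm.statistic:.1f}, "
      f"R2 = {perm.effect_size:.3f}, p = {perm.p_value}")

for stratum in ("CL", "MD"):
    ids = list(meta.index[meta["colonization"] == stratum])
    sub, pest = bc.filter(ids), meta.loc[ids, "pesticide"]
    p = ce.permanova(sub, pest, n_permutations=999, seed=2)
    disp = ce.permdisp(sub, pest, n_permutations=999, seed=3)
    print(f"pesticide within {stratum}: R2 = {p.effect_size:.3f}, "
          f"p = {p.p_value:.3f}; dispersion p = {disp.p_value:.3f}")
# the pesticide signal lives only in the depleted stratum and is small —
# exactly the pattern the planted low-abundance opportunist shifts create.
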
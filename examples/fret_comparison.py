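"""De-quenching FRET: per-cell efficiencies and a two-group comparison.

Simulates ~20 cells per variant at the reported efficiencies (20% for
232I, 40% for 232T) with 10% intensity noise, summarizes each group and
tests the difference.
"""

from fcgrkit.fret import compare_groups, summarize_group
from fcgrkit.synthetic import simulate_fret_cells

low = simulate_fret_cells(0.20, n_cells=20, noise_cv=0.10, seed=1, group="232I")
high = simulate_fret_cells(0.40, n_cells=20, noise_cv=0.10, seed=2, group="232T")

for cells in (low, high):
    s = summarize_group(cells)
    print(f"{s.group}: n = {s.n_cells}, mean E = {100*s.mean_e:.1f}% "
          f"+/- {100*s.sem_e:.1f}% (SEM), median = {100*s.median_e:.1f}%")

cmp = compare_groups(high, low)
print(f"\nfold change (232T/232I) = {cmp.fold_change:.2f}, "
      f"Welch t = {cmp.statistic:.2f}, p = {cmp.p_value:.2g}")
print("\nA ~2-fold higher efficiency in 232T means its ectodomain donor sits "
      "closer to the membrane acceptor dye - a more recumbent conformation.")
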
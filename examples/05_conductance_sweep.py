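"""A small conductance-space sweep with firing-parameter maps.

Runs a reduced (5 x 6) grid over (Kv7.4, Kv1.1) conductances — the full
map is 21 x 51 = 1071 combinations per Kvb2 mode — and prints the
phenotype map plus the threshold map.  Thresholds grow along the Kv1 axis
while spike counts fall along the Kv7.4 axis.
"""

from mauthner import SweepGrid, run_sweep

grid = SweepGrid(kv74_axis_nS=(0, 500, 1000, 1500, 2000),
                 kv1_axis_nS=(0, 200, 400, 600, 800, 1000))
result = run_sweep(grid)

print(f"{grid.n_points} grid points (default full grid: "
      f"{SweepGrid().n_points} per Kvb2 mode)\n")
print("phenotype map (rows: gKv7.4 nS, cols: gKv1.1 nS):")
print(result.map2d("threshold_pA").to_string(float_format="%.0f"))
print()
pheno = result.table.pivot(index="gKv74_nS", columns="gKv1_nS",
                           values="phenotype")
print(pheno.to_string())
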
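"""Flux balance analysis and flux variability analysis.

A toy network with two parallel branches shows the difference between the
two: FBA returns one optimal flux distribution (the branch split is
arbitrary), while FVA reports, per reaction, the whole range of fluxes
compatible with optimal growth — exposing which fluxes the stoichiometry
actually pins down.
"""

from emuflux.fixtures import parallel_paths_network
from emuflux.flux_models import fba, fva

net = parallel_paths_network(uptake=10.0)
best = fba(net)
print(f"FBA optimum (sink flux): {best.objective_value:.1f} mmol/gDW/h")
for rid, flux in best.items():
    print(f"  {rid}: {flux.net:.2f}")

print("FVA ranges at 100% of the optimum:")
for rid, r in fva(net, fraction=1.0).items():
    pinned = "pinned" if r.width < 1e-6 else "free"
    print(f"  {rid}: [{r.lo:5.2f}, {r.hi:5.2f}]  ({pinned})")
print("the two branches each span [0, 10]: any split achieves the optimum")
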
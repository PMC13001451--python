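"""dN/dS estimation and the positive-selection site test on simulated data.

A codon family is simulated with 20% of sites at omega = 4; the one-ratio
(M0) fit summarizes whole-gene constraint, NG86 cross-checks a pair, and
the two-vs-three-class LRT asks whether any site class has omega > 1.
"""

import numpy as np

from orthounmask import Tree, m0_fit, ng86_dnds, sites_test
from orthounmask.synthetic_data import SimulationConfig, simulate_codon_family

tree = Tree.from_newick(
    "(((a:0.4,b:0.4):0.2,(c:0.4,d:0.4):0.2):0.1,"
    "((e:0.4,f:0.4):0.2,(g:0.4,h:0.4):0.2):0.1);")
cfg = SimulationConfig(tree=tree, seed=42, model="codon", n_sites=300,
                       omega_classes=((0.8, 0.2), (0.2, 4.0)))
caln, true_classes = simulate_codon_family(cfg)

m0 = m0_fit(caln, tree)
print(f"M0: omega={m0.omega:.3f}, kappa={m0.kappa:.2f}, lnL={m0.logL:.1f}")

pair = ng86_dnds(caln.rows[0][1], caln.rows[1][1])
print(f"NG86 (a vs b): dN={pair.dN:.3f}, dS={pair.dS:.3f}, "
      f"omega={pair.omega:.3f}")

res = sites_test(caln, tree)
true_pos = set(np.nonzero(true_classes == 1)[0].tolist())
recall = len(set(res.flagged_sites) & true_pos) / len(true_pos)
print(f"sites test: LRT={res.LRT_stat:.1f}, p={res.p_value:.2g}, "
      f"{len(res.flagged_sites)} sites flagged (NEB > 0.9), "
      f"recall of true positive sites {recall:.2f}")

print("-> M0's single omega averages over classes (~0.2 background with a"
      " positive minority); the LRT detects the omega>1 class directly.")
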
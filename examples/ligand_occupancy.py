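"""Equilibrium EGF occupancy of EGFR under the two-affinity-site model.

Cell-surface EGFR has a high-affinity minority (Kd ~0.1 nM, ~10% of sites)
and a low-affinity majority (Kd 2-6 nM, ~90%). This computes the occupied
fraction of binding sites at physiological and saturating EGF doses.
"""

import nanodomain as nd

for conc in (5.0, 10.0, 100.0, 200.0):
    nm = nd.ngml_to_nM(conc)
    lo = nd.occupancy(nd.two_site_egf_model(kd_low=6.0), conc)
    hi = nd.occupancy(nd.two_site_egf_model(kd_low=2.0), conc)
    print(f"{conc:6.0f} ng/mL = {nm:6.2f} nM   occupancy {100*lo:4.0f}-{100*hi:3.0f} %")
# Physiological doses (5-10 ng/mL) occupy only ~10-40% of sites, while
# 100 ng/mL drives ~70-90% occupancy — the regime where receptor
# oligomerization is disrupted by depletion of unliganded receptors.
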
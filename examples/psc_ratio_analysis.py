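"""EPSC/IPSC charge analysis around SWR events.

Simulates voltage-clamp current traces with one biexponential postsynaptic
current per SWR (EPSCs at -70 mV, IPSCs at 0 mV), integrates each event's
charge, and reports the pre/post-gamma change of the EPSC-to-IPSC ratio for
an injected excitation-dominant effect (EPSC x2.0, IPSC x1.3).
"""

import numpy as np

from swrgamma import SimConfig, epsc_ipsc_ratio, psc_area, simulate_psc_trace

cfg = SimConfig(duration=300.0, fs=5000.0, quiet_pre=140.0, gamma_len=20.0,
                swr_rate=1.0, seed=3)

events = {}
for pol, post_scale in (("EPSC", 2.0), ("IPSC", 1.3)):
    trace, truth = simulate_psc_trace(cfg, pol, event_area_mean=0.5,
                                      post_scale=post_scale)
    for epoch in ("quiet_pre", "quiet_post"):
        events[(pol, epoch)] = [
            psc_area(trace, (e.t_start, e.t_end), polarity=pol)
            for e in truth.events_in(epoch)]

for pol in ("EPSC", "IPSC"):
    pre = np.mean([e.area for e in events[(pol, "quiet_pre")]])
    post = np.mean([e.area for e in events[(pol, "quiet_post")]])
    print(f"{pol}: mean charge {pre:.3f} -> {post:.3f} pA*s "
          f"({100 * (post - pre) / pre:+.1f}%)")

r_pre = epsc_ipsc_ratio(events[("EPSC", "quiet_pre")], events[("IPSC", "quiet_pre")])
r_post = epsc_ipsc_ratio(events[("EPSC", "quiet_post")], events[("IPSC", "quiet_post")])
print(f"EPSC-to-IPSC ratio: {r_pre:.2f} -> {r_post:.2f} "
      f"(x{r_post / r_pre:.2f}, injected 2.0/1.3 = x1.54)")
print("the ratio indexes net cellular excitability: a rise means excitation")
print("outgrew inhibition after the gamma episode.")
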
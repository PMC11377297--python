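"""One simulated force-displacement (FD) curve.

The trace rises along the worm-like-chain stretching branch and drops to
zero at the stochastic rupture, mirroring a single optical-tweezers
pulling record.
"""

from ringrupture import BondModel, PullingProtocol, generate_fd_trace

trace = generate_fd_trace(PullingProtocol(seed=35), BondModel(0.0027, 1.23))
rupture = trace.attrs["rupture_force_pn"]
pre = trace[trace.force_pN > 0]
print(f"trace: {len(trace)} steps, rupture at {rupture:.1f} pN "
      f"after {pre.time_s.iloc[-1]:.1f} s "
      f"({pre.displacement_nm.iloc[-1] / 1000:.2f} um displacement)")
print("\nforce along the pull (every 500th step):")
for _, row in trace.iloc[::500].iterrows():
    bar = "#" * int(row.force_pN)
    print(f"  x = {row.displacement_nm / 1000:5.2f} um  F = {row.force_pN:5.1f} pN  {bar}")
print("\nThe force stays near zero until the chain tightens, then rises")
print("steeply until the ring disengages and the tether is lost.")
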
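"""Life-table parameters across the rearing temperatures.

Builds deterministic age schedules (rate summation + Euler-Lotka) at
each constant temperature and prints rm, Ro, GRR, Tc, lambda and Dt.
"""

from fawphen import life_table_parameters, reference_model

model = reference_model()

print(f"{'T (C)':>6} {'rm (1/d)':>9} {'Ro':>8} {'GRR':>8} {'Tc (d)':>8} "
      f"{'lambda':>8} {'Dt (d)':>7}")
for T in (20.0, 25.0, 28.0, 30.0, 32.0):
    p = life_table_parameters(model, T)
    print(f"{T:6.0f} {p.rm:9.4f} {p.Ro:8.1f} {p.GRR:8.1f} {p.Tc:8.2f} "
          f"{p.lam:8.4f} {p.Dt:7.3f}")

print("\nrm peaks near 28 C: populations grow fastest there, doubling in "
      "about 3 days; at 20 and 32 C growth is roughly half as fast.")
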
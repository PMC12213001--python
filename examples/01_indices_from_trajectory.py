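"""Compute the six movement indices for a hand-built walking path.

A two-segment right-angle path (3 m east, then 4 m north) has total length
L = 7 m and net displacement D = 5 m, so the straightness index TS = D/L =
5/7.  S2 and TE are computed after rediscretizing the path to constant 5 cm
steps; DC is the mean absolute turning rate in degrees per second.
"""

from sinupath import TrajectoryPath, compute_all

path = TrajectoryPath.from_xy("demo", x=[0, 3, 3], y=[0, 0, 4],
                              t=[0, 60, 140])
m = compute_all(path, R=0.05)

print(f"path length L   = {m.length:.3f} m")
print(f"displacement D  = {m.net_displacement:.3f} m")
print(f"straightness TS = {m.TS:.4f}  (D/L; 1 would be a perfectly direct walk)")
print(f"sinuosity S2    = {m.S2:.4f} rad m^-1/2  (larger = more tortuous)")
print(f"Emax TE         = {m.TE:.2f}  (dimensionless; larger = straighter)")
print(f"DC              = {m.DC:.3f} deg/s  (mean turning rate)")
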
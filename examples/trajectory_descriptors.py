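"""Geometry descriptors on a toy membrane-receptor trajectory.

Builds a 200-frame trajectory with known ground truth (TM tilt 40 deg,
ectodomain inclination 40 deg, C1-domain height 30 A, stalk span 11 A)
plus 0.5 A atomic jitter, then recovers each descriptor per frame and
summarizes its distribution.
"""

from fcgrkit import trajgeom as tg
from fcgrkit.synthetic import SyntheticTrajectorySpec, build_toy_trajectory

spec = SyntheticTrajectorySpec(
    tilt_deg=40.0, incl_deg=40.0, d_c1=30.0, span_s218_p221=11.0,
    n_frames=200, jitter_sd=0.5, seed=3,
)
frames = build_toy_trajectory(spec)

def plane_of(frame):
    return tg.membrane_plane(frame, "M:*:P", orient_toward="A:130-132")

descriptors = {
    "TM tilt (deg)": lambda f: tg.helix_tilt_angle(f, "A:222-248:CA", plane_of(f)),
    "inclination (deg)": lambda f: tg.ectodomain_inclination(f, plane_of(f)),
    "C1 height (A)": lambda f: tg.domain_membrane_distance(f, "A:50-80:CA", plane_of(f)),
    "S218-P221 span (A)": lambda f: tg.segment_normal_length(f, 218, 221, plane_of(f)),
}

print(f"{len(frames)} frames, jitter sd = {spec.jitter_sd} A\n")
for name, func in descriptors.items():
    series = tg.compute_series(frames, func, name, name.split("(")[1][:-1])
    s = series.summary()
    bin_width = 2.0 if "deg" in name else 0.5
    h = series.histogram(bin_width=bin_width)
    print(f"{name:20s} mean = {s['mean']:7.2f}  sd = {s['sd']:5.2f}  "
          f"mode bin = {h.mode:6.2f}")

frame = frames[0]
pair = tg.atom_pair_distance(frame, "A:232:OG1", "A:228:O")
print(f"\nT232 OG1 - V228 O distance: {pair.distance:.2f} A "
      f"(H-bond at 3.5 A cutoff: {pair.is_hbond})")
print("\nEach mean sits on its construction value; the scatter reflects "
      "only the injected atomic jitter.")
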
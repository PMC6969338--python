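"""Framewise and absolute displacement from a motion-parameter file.

Builds a tiny 6-column .par file (3 rotation columns in radians, then 3
translation columns in mm, one row per volume), reads it back, and
prints the run's motion summary.
"""

import tempfile
from pathlib import Path

from twinscan import read_motion_par, summarize_run

PAR_TEXT = """\
0       0  0       0    0     0
0.001   0  -0.002  0.1  -0.2  0.3
0.001   0  -0.002  0.1  -0.2  0.3
0.002   0  -0.001  0.3  -0.1  0.5
"""

with tempfile.TemporaryDirectory() as tmp:
    par = Path(tmp) / "sub01_snat1.par"
    par.write_text(PAR_TEXT)
    trace = read_motion_par(par, subject_id="sub01", run_label="snat1")
    summary = summarize_run(trace)

print(f"volumes:            {summary.n_volumes}")
print(f"mean FD:            {summary.mean_fd:.4f} mm")
print(f"mean AD (x/y/z):    {summary.mean_ad_x:.3f} / "
      f"{summary.mean_ad_y:.3f} / {summary.mean_ad_z:.3f} mm")
print(f"max |displacement|: {summary.max_abs_per_axis:.3f} mm")
print(f"frames > 0.3 mm:    {summary.frac_flagged_03:.0%}")

# The first volume-to-volume step moves (0.1, -0.2, 0.3) mm and rotates
# (0.001, 0, -0.002) rad: FD = 0.6 mm + 50 mm * 0.003 rad = 0.75 mm.
# AD is measured per axis against the middle volume of the run, so a
# constant head offset contributes nothing.
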
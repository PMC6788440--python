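"""Effort accounting on the published survey tables.

Reconstructs a capture-level survey from the published per-location
capture/effort totals, recomputes trap success (captures per 100 trap
nights) with and without the arboreal/pitfall side surveys, and
recomputes camera-trap relative abundance.  The printed percentages
should match the published tables exactly.
"""
import elevdiv as ed
from elevdiv.datasets import load_camera_table, trap_success_survey

ds = trap_success_survey()
print("Including arboreal and pitfall traps:")
print(ed.trap_success(ds, "mountain")[["mountain", "n_captures", "trap_nights", "percent"]])

flt = ed.filter_records(ds)  # drops arboreal/pitfall captures and effort
print("\nExcluding arboreal and pitfall traps:")
print(ed.trap_success(flt, "mountain")[["mountain", "n_captures", "trap_nights", "percent"]])

cam = load_camera_table()
rates = ed.camera_relative_abundance(cam[~cam["denominator_ambiguous"]])
print("\nCamera-trap relative abundance (series per 100 camera nights):")
print(rates[["camera_id", "species", "n_series", "camera_nights", "rate_per_100_nights"]])
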
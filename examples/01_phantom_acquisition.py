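"""Simulate confocal acquisition of a growing thrombus phantom.

Builds a lobed semi-ellipsoid growing ~1 % volume per second and scans it
with the realistic schedule (1.2 s bottom-up scan + 2.3 s transfer, 0.5 μm
slices, 0.31 μm/pixel).  The printed timestamps show the time skew: the
top slice of each stack is 1.2 s younger than its bottom slice, so a
growing object is not imaged at a single instant.
"""

from thrombotrace import AcquisitionSchedule, acquire_zstacks, make_lobed_phantom

phantom = make_lobed_phantom(growth_rates=0.01 / 3, kind="exponential", seed=0)
schedule = AcquisitionSchedule(width_px=288, height_px=64, n_slices=70, n_stacks=3)
stacks = acquire_zstacks(phantom, schedule)

print(f"phantom volume at t=0:   {phantom.volume_um3(0.0):8.0f} μm³")
print(f"phantom volume at t=7 s: {phantom.volume_um3(7.0):8.0f} μm³  (growth)")
for st in stacks:
    print(
        f"stack {st.index}: {len(st)} slices, "
        f"t = {st.t_start:6.2f} … {st.t_end:6.2f} s "
        f"(skew across stack: {st.t_end - st.t_start:.2f} s)"
    )
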
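"""Build the threaded bone-implant channel and inspect its zones.

Rasterizes the 10 x 1.5 mm channel with ten 1.0 x 0.5 mm triangular
threads and reports the fluid/solid split and the interfacial-zone area
(the region between the implant body and the thread-peak line, where
infiltration is measured).
"""

from implantflow import Zone, build_layout, rasterize

layout = build_layout()            # reference implant dimensions
for cell in (0.05, 0.025):
    mesh = rasterize(layout, cell)
    print(f"cell {cell} mm: {mesh.nx} x {mesh.ny} cells, "
          f"{mesh.n_fluid} fluid")
    print(f"  fluid area        = {mesh.fluid_area():.4f} mm^2 "
          f"(exact 15 - 2.5 = 12.5)")
    print(f"  interfacial area  = {mesh.zone_area(Zone.INTERFACIAL):.4f} mm^2 "
          f"(exact 2.5)")
    print(f"  boundary faces    = {dict((t.name, n) for t, n in mesh.boundary_face_counts().items())}")
print()
print("The rasterized areas converge to the exact polygon values as the")
print("cell size shrinks; the interfacial zone holds ~20% of the fluid,")
print("which anchors the infiltration-rate scale of the full simulation.")
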
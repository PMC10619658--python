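"""Build the default virtual cotton plant and export its mesh.

The generator places 16 straight fruiting branches on stem nodes 5-20 of
a 130 cm, 20-segment main stem, hangs three leaves per branch, and draws
leaf shapes from three classes (ovate / 3-lobed / 5-lobed at 20/55/25%)
whose planform areas equal the measured windward areas.
"""
from collections import Counter

from canopyflow import PlantSpec, generate_plant, export_mesh, mesh_area

spec = PlantSpec(rng_seed=0)
plant = generate_plant(spec)

print(f"leaves: {len(plant.leaves)}  branches: {len(plant.branch_meshes)}")
print("kinds:", dict(Counter(lf.kind for lf in plant.leaves)))
print("layers:", dict(Counter(lf.layer_id for lf in plant.leaves)))
print(f"bounding-box height: {plant.bounding_box_height:.1f} mm")
one = plant.leaves[0]
print(f"first leaf: {one.kind}, blade area {mesh_area(one.mesh):.2f} mm^2, "
      f"attached at {one.attach_height:.0f} mm (layer {one.layer_id})")

path = export_mesh(plant, "scratch_plant.stl")
print(f"exported -> {path}")
# The kind counts follow largest-remainder rounding of the 20/55/25%
# fractions; each blade's mesh area equals its class's windward area.
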
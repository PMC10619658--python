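"""One cotton leaf in a downward air jet: deflection grows with speed.

A single-leaf plant is immersed in the lattice fluid; the two-way
immersed-boundary coupling lets the jet bend the leaf while the leaf
blocks the jet.
"""
from canopyflow import CouplingConfig, Material, PlantSpec, generate_plant
from canopyflow.coupling import run_simulation

plant = generate_plant(PlantSpec(n_leaves=1, rng_seed=2,
                                 leaf_outline_points=32))
for speed in (2.0, 4.0):
    cfg = CouplingConfig(inlet_speed=speed, n_lattice=24, duration=0.06,
                         output_interval=0.005)
    rec = run_simulation(plant, Material(damping=30.0), cfg)
    dz = rec.frames[-1].nodes[:, 2] - rec.initial_frame.nodes[:, 2]
    log = rec.stability_log[-1]
    print(f"inlet {speed:.0f} m/s: max downward leaf excursion "
          f"{-1e3 * dz.min():.1f} mm, max lattice velocity {log['max_u_lat']:.3f}")
# The downward excursion increases monotonically with the inlet speed;
# the lattice Mach number stays far below the incompressible limit.
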
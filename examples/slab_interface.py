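"""Locate the air/water interface of a synthetic slab and classify the ion.

Generates a small periodic water slab with a chloride ion 2 A below the
upper surface, computes the mass density profile, fits the Gibbs dividing
surface (GDS), classifies the ion environment under the GDS-3 A rule and
carves the two-shell cluster around it.
"""

import numpy as np

import ioneda as io

spec = io.SlabSpec(box=(18.0, 18.0, 60.0), slab_thickness=24.0,
                   density=0.997, ion="Cl-", depth=2.0, n_frames=4, seed=11)
frames = io.generate_slab(spec)
print(f"slab: {len(frames)} frames, {len(frames[0].atoms)} atoms each")

profile = io.mass_density_profile(frames, axis="z", bin_width=1.0)
gds = io.locate_gds(profile)
print(f"bulk density {gds.bulk_density:.3f} g/cm^3 "
      f"(target {spec.density}); GDS faces at z = {gds.z_lower:.2f} / "
      f"{gds.z_upper:.2f} A, widths {gds.width_lower:.2f} / "
      f"{gds.width_upper:.2f} A")

ion, _ = io.detect_fragments(frames[0].atoms, "Cl-")
ion_z = io.center_of_mass([frames[0].atoms[i] for i in ion.indices])[2]
env = io.classify_environment(ion_z, gds, cutoff=3.0)
print(f"ion at z = {ion_z:.2f} A, depth below GDS "
      f"{gds.z_upper - ion_z:.2f} A -> classified '{env}'")

snap = io.carve_two_shell_cluster(frames[0], ion, r_cut=6.0)
print(f"carved cluster: {snap.n_waters} waters within 6.0 A of the ion")

rdf = io.compute_rdf(frames, "Cl", "O", dr=0.25, r_max=8.0)
peak = rdf.r[np.argmax(rdf.g)]
print(f"Cl-O RDF peaks near {peak:.2f} A "
      "(first hydration shell of the generated geometry)")
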
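# Default Go-model parameters: this implementation's pinned defaults.
# Copy, edit, and pass to `ktgo build --config` or GoParams.from_yaml().
# Units: kcal/mol/A^2 (bond k), kcal/mol/rad^2 (angle/improper k),
# kcal/mol (dihedral barriers, epsilons), Angstrom (lengths).

# bonded terms: equilibria always come from the native geometry
bond_k_backbone: 50.0      # CA(i)-CA(i+1); softer than an all-atom bond
bond_k_sidechain: 50.0     # CA(i)-SC(i)
angle_k: 30.0
dihedral_k_helix: 1.0      # backbone CA dihedrals in helical segments
dihedral_k_strand: 1.0     # ... in strand segments
dihedral_k_coil: 0.3       # ... in coil (secondary structure sets stiffness)
improper_k: 20.0           # chirality barrier on (CA-, CA+, CA, SC)

# native contacts
contact_cutoff: 4.5        # SC-SC crystal distance defining a contact (A)
min_separation: 3          # minimum |i-j| for a contact pair
mj_calibration: 0.6        # kcal/mol per statistical-potential unit (~RT)

# backbone hydrogen bonds (weakly attractive CA-CA wells)
hbond_distance: 3.5        # donor N ... acceptor O cutoff (A)
hbond_h_distance: 2.5      # amide H ... O cutoff (H rebuilt if absent)
hbond_min_separation: 3
hbond_eps_fraction: 0.5    # epsilon_hb = fraction x weakest contact epsilon
hbond_eps_floor: 0.1       # used when a model has no contacts (kcal/mol)

# excluded volume for all non-native pairs: eps * (sigma/r)^12
eps_repulsive: 1.0
sigma_ca: 3.8
sigma_sc: 3.6

# nonbonded truncation (CHARMM-style energy switching)
switch_r_on: 18.0
switch_r_off: 23.0
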
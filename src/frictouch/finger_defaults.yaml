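# Calibrated default parameters of the axisymmetric fingertip model
# (frictouch.mechanics.FingerModelParams). Version 2.
#
# Calibrated so that a press to 3 N reproduces the reference fingertip
# behaviour: contacted-skin divergence ~0.04 at mu=0.1 and ~0.02 at
# mu=0.6, ~40% higher peak tangential interfacial stress at mu=0.6,
# and a friction-invariant normal-stress profile.
# Units: mm, N, kg, s.
n_nodes: 41
finger_radius: 8.0
skin_stiffness_normal: 5.0       # plate contact penalty, N/mm per node
skin_stiffness_tangential: 1.0   # elastoplastic stick-spring, N/mm
membrane_stiffness: 4.5          # neighbour Kelvin-Voigt spring, N/mm
bulk_stiffness: 0.05             # pulp spring (linear part), N/mm per node
bulk_stiffening: 0.02            # pulp cubic strain-stiffening, N/mm^3
bulk_mode: radial
bulk_radial_fraction: 0.45       # anisotropic pulp shear compliance
pulp_pressure_stiffness: 0.0
kv_damping: 0.01
contact_damping: 0.05
mass_damping: 0.02
node_mass: 0.002
bone_mass: 0.02
mu: 0.1
target_force: 3.0
ramp_rate: 3.6                   # N/s, typical human pressing rate
dt: 2.0e-5
equilibrium_tol: 0.05
onset_force_threshold: 0.02      # N, optical-detection analogue
theta_max_deg: 75.0
apex_clearance: 0.05
max_steps: 700000
settle_window: 100
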
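# Model configuration (YAML)

A model file is a single YAML document with seven sections. The shipped
planar fixture is the reference example — dump it with:

```python
from fnsgait import planar_biped, save_model
save_model(planar_biped(), "model.yaml")
```

## Sections

```yaml
name: planar_biped
gravity: 9.81            # m/s^2, acts along -y
symmetric: true          # enforce left/right segment symmetry checks

coordinates:             # generalized coordinates, in order
  - {name: pelvis_tx, kind: tx, range: [-1.0, 1.0],
     default_speed_range: [-2.0, 2.0]}
  # kind: tx | ty (world translations, root segment only) | rz (revolute)
  # range: position bounds (m or rad); default_speed_range: speed bounds
  # used when no reference-motion ranges apply

segments:                # rigid bodies, parents listed first
  - name: pelvis
    mass: 10.82          # kg
    inertia: 0.08        # kg m^2 about the COM (planar)
    length: 0.15         # m, bookkeeping
    parent: ground       # or another segment name
    parent_offset: [0.0, 0.0]   # joint anchor in the parent frame, m
    com_offset: [-0.02, 0.02]   # COM in the local frame, m
    coordinates: [pelvis_tx, pelvis_ty, pelvis_rot]  # joint coordinates

muscles:                 # Hill-type muscle-tendon units
  - name: iliopsoas_l
    max_isometric_force: 1500.0   # N
    optimal_fiber_length: 0.12    # m
    tendon_slack_length: 0.10     # m
    pennation: 0.0                # rad
    activation_time_constant: 0.015   # s
    deactivation_time_constant: 0.060 # s
    moment_arms: {hip_l: 0.040}   # m per coordinate; + shortens the muscle
    reference_length: null        # l_MT at q=0; default slack + optimal
    group_id: iliopsoas_l
    side: left

muscle_groups:           # one stimulation channel drives 1-3 elements
  - {gid: vasti_l, members: [vasti_med_l, vasti_lat_l], side: left,
     method: implanted}  # method: implanted | surface

contact_spheres:
  - parent_segment: foot_l
    offset: [-0.06, -0.05]   # center in the segment frame, m
    radius: 0.02             # m
    stiffness: 1.0e5         # N/m^exponent
    dissipation: 2.0         # s/m
    exponent: 1.5
    mu_static: 0.8
    mu_dynamic: 0.8
    mu_viscous: 0.5
    smoothing: 1.0e-4        # m, penetration smoothing scale
    transition_velocity: 0.05  # m/s, friction regularization

actuators:               # reserve / volitional force-torque actuators
  - {target_coordinate: pelvis_tx, kind: force, max_magnitude: 250.0,
     cost_weight_tag: penalized}   # penalized | normal

markers:                 # tracking markers
  - {name: SACR, segment: pelvis, offset: [-0.08, 0.05], weight: 10.0,
     bony_prominence: true}        # bony markers default to 10x weight

leg_landmarks:           # leg-clearance constraint geometry
  left_segment: shank_l
  left_offset: [0.0, -0.2]
  left_lateral: 0.10     # fixed out-of-plane position, m
  right_segment: shank_r
  right_offset: [0.0, -0.2]
  right_lateral: -0.10
```

Constraints: world translations (`tx`/`ty`) are only allowed on the root
segment; every other joint is a revolute about the segment's anchor point.
Left/right pairing (for symmetry constraints and mirrored states) is by the
`_l`/`_r` naming convention. Total mass is the sum of segment masses; with
`symmetric: true`, contralateral segments must have matching mass and
inertia.
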
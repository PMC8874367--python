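# Default relay-conduit study configuration.
# Sections and keys mirror GeometrySpec / ReleaseSystemSpec / SolverConfig;
# any key omitted keeps its library default, unknown keys are rejected.

geometry:
  ngc_diameter: 2.0        # mm, outer conduit diameter
  channel_diameter: 0.34   # mm
  n_channels_3d: 9         # channels in the 3D conduit (area bookkeeping)
  n_channels_2d: 3         # channel lumens visible in the 2D section
  wall_thickness: 0.2      # mm
  cavity_length: 1.0       # mm, each of the three relay cavities
  segment_length: 2.17     # mm, conduit length between adjacent cavities

release_system:
  kind: single_layer_microsphere
  microsphere_diameter: 0.1   # mm
  microsphere_quantity: 8     # spheres per selected cavity
  adjacent_distance: 0.2      # mm, center-to-center
  placements: [middle]

solver:
  dt: 0.5                  # s
  inlet1_speed: 1.0e-6     # m/s, physiological interstitial-fluid velocity
  advection_scheme: first_order_upwind
  drift_closure: zero_slip
  gdnf_diffusivity: 0.0    # m^2/s
  depth_mm: 1.0            # out-of-plane depth for volume conversions
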
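# Temporal expression archetypes over the four differentiation time
# points D-2, D0, D3, D9 (FPKM levels of the noise-free template).
#
# The 19 shapes cover: four stable cohorts (two low, two high), three
# cohorts induced from zero FPKM at successive time points, one cohort
# expressed throughout and further up-regulated, three cohorts repressed
# to zero at successive time points, and eight transient single-pulse or
# oscillatory shapes. Levels are free parameters of the simulator chosen
# so that "strong" cohorts exceed "weak" ones by >= 10x and all pairs of
# templates are well separated in log(FPKM + 1) space.
archetypes:
  stable_low_1:        {shape: stable,    fpkm: [1, 1, 1, 1]}
  stable_low_2:        {shape: stable,    fpkm: [3, 3, 3, 3]}
  stable_high_1:       {shape: stable,    fpkm: [30, 30, 30, 30]}
  stable_high_2:       {shape: stable,    fpkm: [100, 100, 100, 100]}
  induced_d0:          {shape: induced,   fpkm: [0, 20, 20, 20]}
  induced_d3:          {shape: induced,   fpkm: [0, 0, 20, 20]}
  induced_d9:          {shape: induced,   fpkm: [0, 0, 0, 20]}
  expressed_up:        {shape: up,        fpkm: [10, 20, 40, 80]}
  repressed_d0:        {shape: repressed, fpkm: [20, 0, 0, 0]}
  repressed_d3:        {shape: repressed, fpkm: [20, 20, 0, 0]}
  repressed_d9:        {shape: repressed, fpkm: [20, 20, 20, 0]}
  pulse_up_d0:         {shape: transient, fpkm: [5, 50, 5, 5]}
  pulse_up_d3:         {shape: transient, fpkm: [5, 5, 50, 5]}
  pulse_down_d0:       {shape: transient, fpkm: [50, 5, 50, 50]}
  pulse_down_d3:       {shape: transient, fpkm: [50, 50, 5, 50]}
  osc_up_down:         {shape: transient, fpkm: [5, 50, 5, 50]}
  osc_down_up:         {shape: transient, fpkm: [50, 5, 50, 5]}
  transient_up_long:   {shape: transient, fpkm: [5, 40, 40, 5]}
  transient_down_long: {shape: transient, fpkm: [40, 5, 5, 40]}
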
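# Demo world: a 12x12 grid, 2000-2004. The mosaic interleaves forest (1),
# shrub/grass (2), plantation (3) and water (5) so every category is
# represented in the supervised set with comparable spatial context.
# Eight forest cells convert to plantation in 2002, and one peat cell burns
# in 2002 and again (shallower) in 2003.
width: 12
height: 12
year_start: 2000
year_end: 2004
base: [1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5,
       1,2,1,3,1,5,1,2,1,3,1,5]
transitions:
  - {cells: [0, 2, 4, 6, 8, 10, 12, 14], year: 2002, to: 3}
fires:
  - {cell: 75, year: 2002, days: [230, 231, 232], confidence: high}
  - {cell: 75, year: 2003, days: [240], confidence: nominal}
peat_cells: [75, 76, 77, 87, 88, 89]
region_id: [0,0,0,0,0,0,0,0,0,0,0,0,
            0,0,0,0,0,0,0,0,0,0,0,0,
            0,0,0,0,0,0,0,0,0,0,0,0,
            0,0,0,0,0,0,0,0,0,0,0,0,
            0,0,0,0,0,0,0,0,0,0,0,0,
            0,0,0,0,0,0,0,0,0,0,0,0,
            1,1,1,1,1,1,1,1,1,1,1,1,
            1,1,1,1,1,1,1,1,1,1,1,1,
            1,1,1,1,1,1,1,1,1,1,1,1,
            1,1,1,1,1,1,1,1,1,1,1,1,
            1,1,1,1,1,1,1,1,1,1,1,1,
            1,1,1,1,1,1,1,1,1,1,1,1]
# observation and classifier settings
noise_sd: 0.005
cloud_fraction: 0.1
n_days: 24
n_per_class: 12
n_estimators: 60
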
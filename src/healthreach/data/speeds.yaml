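# Default traversal speeds (km/h) per transport mode and surface class.
# Road classes override the underlying landcover class in any cell a road
# crosses. Classes with speed 0 are impassable for that mode.
walk:
  primary_road: 6
  secondary_road: 6
  tertiary_road: 6
  forest: 2
  shrubland: 2
  grassland: 5
  cropland: 4
  flooded: 0
  sparse_vegetation: 3
  bare: 5
  built_up: 5
  water: 0
bicycle:
  primary_road: 12
  secondary_road: 12
  tertiary_road: 12
  forest: 2
  shrubland: 2
  grassland: 5
  cropland: 4
  flooded: 0
  sparse_vegetation: 3
  bare: 12
  built_up: 12
  water: 0
drive:
  primary_road: 100
  secondary_road: 50
  tertiary_road: 30
  forest: 2
  shrubland: 2
  grassland: 5
  cropland: 4
  flooded: 0
  sparse_vegetation: 3
  bare: 5
  built_up: 5
  water: 0
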
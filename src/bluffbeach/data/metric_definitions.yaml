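# Orientation of each site metric for the beach-function scale bar.
# higher_is_better: larger raw values indicate greater beach function.
# lower_is_better: the metric is inverted before scoring.
# The packaged default inverts only relative encroachment (a bluff/armor toe
# below MHHW truncates the upper beach); every orientation can be overridden
# in a run config.
metrics:
  - {name: "% Wrack Cover", orientation: higher_is_better, units: "%"}
  - {name: "% Terrestrial Wrack", orientation: higher_is_better, units: "%"}
  - {name: "Wrack Depth (cm)", orientation: higher_is_better, units: "cm"}
  - {name: "Wrack Width (m)", orientation: higher_is_better, units: "m"}
  - {name: "Log Count", orientation: higher_is_better, units: "count"}
  - {name: "Width of Log Line (m)", orientation: higher_is_better, units: "m"}
  - {name: "Count Partially Buried Logs", orientation: higher_is_better, units: "count"}
  - {name: "Fallen Tree Count", orientation: higher_is_better, units: "count"}
  - {name: "Total Fish Density (100m-2)", orientation: higher_is_better, units: "100 m^-2"}
  - {name: "Juvenile Salmon Density (100m-2)", orientation: higher_is_better, units: "100 m^-2"}
  - {name: "Forage Fish Density (100m-2)", orientation: higher_is_better, units: "100 m^-2"}
  - {name: "Juv. Salmon Feeding Observations (%)", orientation: higher_is_better, units: "%"}
  - {name: "% Overhanging Vegetation", orientation: higher_is_better, units: "%"}
  - {name: "% Supratidal Vegetation", orientation: higher_is_better, units: "%"}
  - {name: "Dunegrass Patch Width (m)", orientation: higher_is_better, units: "m"}
  - {name: "Native Vegetation Taxa Richness", orientation: higher_is_better, units: "count"}
  - {name: "Fallout Trap Taxa Richness", orientation: higher_is_better, units: "count"}
  - {name: "Fallout Trap Density (m-2)", orientation: higher_is_better, units: "m^-2"}
  - {name: "Biota Taxa Richness", orientation: higher_is_better, units: "count"}
  - {name: "% Eelgrass", orientation: higher_is_better, units: "%"}
  - {name: "Beach Slope (m/m) Toe-MSL", orientation: higher_is_better, units: "m/m"}
  - {name: "Beach Width (m) Toe-MLLW", orientation: higher_is_better, units: "m"}
  - {name: "Bluff Height (m)", orientation: higher_is_better, units: "m"}
  - {name: "Bluff Exposure (m2)", orientation: higher_is_better, units: "m^2"}
  - {name: "Relative Encroachment (m)", orientation: lower_is_better, units: "m"}
  - {name: "Wave Height (m)", orientation: higher_is_better, units: "m"}
  - {name: "% Sand MHHW", orientation: higher_is_better, units: "%"}
  - {name: "% Sand MLLW", orientation: higher_is_better, units: "%"}
  - {name: "Normalized Sorting MHHW", orientation: higher_is_better, units: "unitless"}
  - {name: "Normalized Sorting MLLW", orientation: higher_is_better, units: "unitless"}
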
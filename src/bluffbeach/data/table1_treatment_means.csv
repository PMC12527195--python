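metric,ProtectHigh,ProtectLow,RestoreHigh,RestoreLow
% Wrack Cover,43.2,41.7,13.7,24.0
% Terrestrial Wrack,10.1,11.3,1.5,2.7
Wrack Depth (cm),2.6,2.0,1.1,1.1
Wrack Width (m),4.0,4.9,3.4,2.4
Log Count,2.6,3.4,0.1,0.0
Width of Log Line (m),1.9,3.3,0.1,0.0
Count Partially Buried Logs,0.8,1.4,0.1,0.0
Fallen Tree Count,13.0,8.8,1.2,0.0
Total Fish Density (100m-2),52.6,2.6,34.6,8.7
Juvenile Salmon Density (100m-2),14.8,0.4,6.2,3.1
Forage Fish Density (100m-2),91.2,0.0,55.5,5.6
Juv. Salmon Feeding Observations (%),5.9,0.0,28.6,50.0
% Overhanging Vegetation,89.8,97.0,42.2,27.6
% Supratidal Vegetation,15.0,34.0,3.2,0.0
Dunegrass Patch Width (m),0.1,1.9,1.1,0.0
Native Vegetation Taxa Richness,12.6,14.0,8.0,6.8
Fallout Trap Taxa Richness,3.4,3.9,3.8,2.9
Fallout Trap Density (m-2),57.7,67.4,73.1,136.3
Biota Taxa Richness,6.5,5.8,6.2,5.2
% Eelgrass,2.0,1.2,1.0,19.1
Beach Slope (m/m) Toe-MSL,0.11,0.12,0.11,0.14
Beach Width (m) Toe-MLLW,41.8,49.7,39.5,39.0
Bluff Height (m),28,10,15,19
Bluff Exposure (m2),1685,370,45,0
Relative Encroachment (m),-0.51,-0.12,0.27,0.41
Wave Height (m),0.48,0.48,0.45,0.48
% Sand MHHW,36,42,59,44
% Sand MLLW,60,64,58,60
Normalized Sorting MHHW,5.4,6.5,2.3,3.8
Normalized Sorting MLLW,3.1,3.3,3.7,2.2
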
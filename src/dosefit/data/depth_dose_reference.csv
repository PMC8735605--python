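# title: Measured and modeled central-axis percent depth dose, 10x10 cm field, SSD 100 cm
# energies: 4MV (published), 6MV (facility), 10MV (facility), 18MV (published)
depth_cm,4MV_measured,4MV_modeled,4MV_error,6MV_measured,6MV_modeled,6MV_error,10MV_measured,10MV_modeled,10MV_error,18MV_measured,18MV_modeled,18MV_error
0.1,38.89,29.46,-24.24,40.12,23.28,-41.97,38.98,17.00,-56.39,32.20,10.94,-66.03
1,98.67,98.75,0.09,98.09,97.12,-0.99,93.91,90.70,-3.42,76.55,78.09,2.01
1.5,98.80,98.92,0.12,100.08,100.08,0.00,97.39,95.82,-1.62,89.55,91.59,2.27
2,98.44,98.59,0.15,99.62,99.56,-0.07,100.02,99.80,-0.22,96.07,97.39,1.38
2.5,96.17,96.32,0.16,98.08,97.82,-0.27,99.22,99.24,0.02,99.01,99.59,0.58
3,93.78,93.93,0.16,96.10,95.66,-0.45,97.96,98.23,0.27,100.00,100.00,0.00
3.5,91.21,91.36,0.16,93.89,93.33,-0.59,96.01,96.52,0.53,99.33,99.48,0.15
4,88.65,88.80,0.17,91.59,90.95,-0.70,94.04,94.63,0.63,98.42,98.43,0.01
4.5,86.10,86.25,0.17,89.25,88.56,-0.78,92.04,92.62,0.63,97.21,97.09,-0.12
5,83.61,83.76,0.18,86.92,86.19,-0.84,90.01,90.57,0.61,95.40,95.57,0.18
5.5,81.14,81.29,0.18,84.62,83.86,-0.89,87.98,88.50,0.59,93.58,93.95,0.39
6,78.78,78.93,0.19,82.35,81.58,-0.93,85.97,86.44,0.55,92.09,92.27,0.20
6.5,76.44,76.59,0.20,80.12,79.35,-0.97,83.87,84.40,0.64,90.15,90.56,0.46
7,74.19,74.34,0.20,77.94,77.17,-0.99,81.38,82.40,1.25,88.34,88.84,0.57
7.5,71.99,72.14,0.21,75.82,75.04,-1.02,79.14,80.43,1.63,86.57,87.12,0.64
8,69.85,70.00,0.21,73.74,72.97,-1.04,77.27,78.50,1.58,84.72,85.41,0.82
8.5,67.78,67.93,0.22,71.71,70.96,-1.05,75.44,76.60,1.54,83.05,83.71,0.80
9,65.75,65.90,0.23,69.74,68.99,-1.07,73.64,74.74,1.50,81.31,82.04,0.89
9.5,63.81,63.96,0.24,67.81,67.08,-1.08,71.89,72.93,1.45,79.68,80.39,0.89
10,61.89,62.04,0.24,65.94,65.22,-1.09,70.16,71.14,1.40,78.07,78.76,0.88
10.5,60.06,60.21,0.25,64.12,63.41,-1.10,68.50,69.43,1.35,76.52,77.16,0.83
11,58.26,58.41,0.26,62.34,61.65,-1.10,66.85,67.72,1.31,74.83,75.58,1.01
11.5,56.54,56.69,0.27,60.61,59.94,-1.11,65.26,66.08,1.26,73.31,74.03,0.99
12,54.84,54.99,0.27,58.93,58.27,-1.12,63.69,64.46,1.21,71.74,72.52,1.07
12.5,53.20,53.35,0.28,57.30,56.66,-1.12,62.17,62.89,1.16,70.28,71.04,1.08
13,51.58,51.73,0.29,55.71,55.08,-1.13,60.68,61.35,1.11,68.81,69.56,1.09
13.5,49.96,50.11,0.30,54.16,53.55,-1.13,59.21,59.84,1.06,67.40,68.14,1.10
14,48.35,48.50,0.31,52.66,52.06,-1.14,57.80,58.38,1.01,65.99,66.72,1.11
14.5,46.73,46.88,0.32,51.20,50.61,-1.14,56.39,56.93,0.96,64.65,65.35,1.09
15,45.11,45.26,0.33,49.77,49.20,-1.14,55.05,55.55,0.91,63.30,63.99,1.08
15.5,43.50,43.65,0.34,48.39,47.84,-1.15,53.72,54.18,0.86,61.99,62.68,1.10
16,41.88,42.03,0.36,47.04,46.50,-1.15,52.44,52.86,0.81,60.68,61.36,1.13
16.5,40.26,40.41,0.37,45.74,45.21,-1.15,51.17,51.56,0.76,59.43,60.10,1.14
17,38.65,38.80,0.39,44.46,43.95,-1.15,49.94,50.30,0.71,58.18,58.84,1.15
17.5,37.03,37.18,0.41,43.23,42.73,-1.16,48.74,49.07,0.66,56.98,57.63,1.15
18,35.42,35.57,0.42,42.03,41.54,-1.16,47.56,47.86,0.61,55.78,56.42,1.15
18.5,33.80,33.95,0.44,40.86,40.38,-1.16,46.43,46.69,0.56,54.61,55.26,1.19
19,32.18,32.33,0.47,39.72,39.26,-1.16,45.30,45.53,0.51,53.45,54.10,1.23
19.5,30.57,30.72,0.49,38.62,38.17,-1.16,44.22,44.42,0.46,52.31,52.99,1.30
20,28.95,29.10,0.52,37.54,37.10,-1.16,43.15,43.32,0.41,51.17,51.88,1.37
20.5,27.34,27.49,0.55,36.50,36.07,-1.16,42.11,42.27,0.36,50.09,50.81,1.42
21,25.72,25.87,0.58,35.48,35.07,-1.17,41.10,41.23,0.31,49.02,49.74,1.47
21.5,24.10,24.25,0.62,34.49,34.09,-1.17,40.11,40.21,0.26,47.99,48.71,1.50
22,22.49,22.64,0.67,33.53,33.14,-1.17,39.14,39.23,0.21,46.97,47.69,1.53
22.5,20.87,21.02,0.72,32.60,32.22,-1.17,38.20,38.26,0.16,46.01,46.71,1.52
23,19.25,19.40,0.78,31.69,31.32,-1.17,37.28,37.32,0.11,45.05,45.72,1.50
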
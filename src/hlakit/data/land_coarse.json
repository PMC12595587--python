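{
  "description": "Synthetic coarse land outlines, hand-digitised for sea-masking global frequency heatmaps at ~1 degree resolution. Vertices are (longitude, latitude) in WGS84 degrees. Deliberately low fidelity: small islands, inland seas and fine coastline detail are absent.",
  "polygons": {
    "north_america": [[-166, 68], [-155, 71], [-130, 70], [-110, 73], [-85, 70], [-75, 62], [-55, 52], [-65, 47], [-70, 44], [-75, 35], [-81, 31], [-80, 25], [-90, 29], [-97, 26], [-97, 16], [-90, 14], [-85, 10], [-79, 9], [-83, 8], [-95, 15], [-105, 19], [-110, 22], [-114, 29], [-125, 40], [-125, 49], [-140, 60], [-152, 59], [-166, 61], [-166, 68]],
    "south_america": [[-79, 9], [-72, 12], [-60, 8], [-50, 0], [-35, -8], [-40, -23], [-48, -28], [-58, -34], [-62, -41], [-68, -50], [-70, -55], [-75, -50], [-72, -40], [-70, -18], [-77, -12], [-81, -5], [-78, 2], [-79, 9]],
    "africa": [[-17, 15], [-16, 23], [-6, 35], [10, 37], [20, 33], [32, 31], [34, 28], [38, 18], [43, 11], [51, 12], [41, -2], [40, -11], [35, -20], [33, -29], [27, -34], [19, -35], [12, -18], [14, -8], [9, 4], [-8, 4], [-13, 9], [-17, 15]],
    "eurasia": [[-10, 37], [-9, 44], [0, 47], [-2, 49], [5, 53], [8, 57], [5, 58], [10, 59], [18, 56], [12, 65], [25, 71], [41, 68], [60, 69], [75, 73], [95, 76], [110, 77], [130, 72], [160, 70], [179, 66], [179, 62], [162, 58], [155, 50], [135, 43], [128, 39], [122, 30], [110, 21], [108, 12], [103, 8], [98, 8], [100, 14], [94, 16], [88, 22], [80, 15], [77, 8], [72, 20], [66, 25], [57, 25], [52, 13], [43, 12], [44, 17], [39, 21], [35, 28], [27, 36], [30, 41], [23, 36], [15, 38], [10, 44], [4, 43], [0, 40], [-6, 36], [-10, 37]],
    "australia": [[114, -22], [113, -26], [115, -35], [129, -32], [138, -35], [147, -38], [150, -37], [153, -28], [146, -19], [142, -11], [136, -12], [130, -12], [122, -17], [114, -22]],
    "greenland": [[-45, 60], [-53, 66], [-55, 70], [-50, 75], [-40, 77], [-30, 75], [-22, 70], [-42, 60]],
    "japan": [[130, 31], [136, 34], [140, 35], [141, 41], [143, 44], [145, 45], [141, 45], [139, 40], [135, 35], [130, 33], [130, 31]],
    "uk": [[-5, 50], [1, 51], [0, 53], [-2, 56], [-4, 58], [-6, 56], [-5, 53], [-5, 50]],
    "madagascar": [[44, -25], [47, -25], [50, -16], [49, -12], [46, -16], [44, -25]],
    "new_guinea": [[131, -1], [138, -2], [146, -6], [150, -10], [143, -9], [135, -4], [131, -1]],
    "borneo_sumatra": [[95, 5], [98, 3], [104, -3], [106, -6], [114, -8], [116, -4], [119, 1], [117, 7], [110, 7], [109, 0], [102, 1], [95, 5]]
  }
}
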
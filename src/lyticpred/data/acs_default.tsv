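# residue state nucleus value_ppm
# Default average chemical shift table: random-coil reference
# values with nominal helix/sheet offsets. Replace with a
# user-supplied table for production use.
A H 15N 122.80
A H 13Ca 55.10
A H 1Ha 3.94
A H 1HN 8.04
A E 15N 125.30
A E 13Ca 51.10
A E 1Ha 4.70
A E 1HN 8.54
A C 15N 123.80
A C 13Ca 52.50
A C 1Ha 4.32
A C 1HN 8.24
C H 15N 117.80
C H 13Ca 60.80
C H 1Ha 4.17
C H 1HN 8.12
C E 15N 120.30
C E 13Ca 56.80
C E 1Ha 4.93
C E 1HN 8.62
C C 15N 118.80
C C 13Ca 58.20
C C 1Ha 4.55
C C 1HN 8.32
D H 15N 119.40
D H 13Ca 56.80
D H 1Ha 4.26
D H 1HN 8.14
D E 15N 121.90
D E 13Ca 52.80
D E 1Ha 5.02
D E 1HN 8.64
D C 15N 120.40
D C 13Ca 54.20
D C 1Ha 4.64
D C 1HN 8.34
E H 15N 119.20
E H 13Ca 59.20
E H 1Ha 3.97
E H 1HN 8.22
E E 15N 121.70
E E 13Ca 55.20
E E 1Ha 4.73
E E 1HN 8.72
E C 15N 120.20
E C 13Ca 56.60
E C 1Ha 4.35
E C 1HN 8.42
F H 15N 119.30
F H 13Ca 60.30
F H 1Ha 4.24
F H 1HN 8.10
F E 15N 121.80
F E 13Ca 56.30
F E 1Ha 5.00
F E 1HN 8.60
F C 15N 120.30
F C 13Ca 57.70
F C 1Ha 4.62
F C 1HN 8.30
G H 15N 107.80
G H 13Ca 47.70
G H 1Ha 3.58
G H 1HN 8.13
G E 15N 110.30
G E 13Ca 43.70
G E 1Ha 4.34
G E 1HN 8.63
G C 15N 108.80
G C 13Ca 45.10
G C 1Ha 3.96
G C 1HN 8.33
H H 15N 117.20
H H 13Ca 57.60
H H 1Ha 4.35
H H 1HN 8.22
H E 15N 119.70
H E 13Ca 53.60
H E 1Ha 5.11
H E 1HN 8.72
H C 15N 118.20
H C 13Ca 55.00
H C 1Ha 4.73
H C 1HN 8.42
I H 15N 118.90
I H 13Ca 63.70
I H 1Ha 3.79
I H 1HN 7.80
I E 15N 121.40
I E 13Ca 59.70
I E 1Ha 4.55
I E 1HN 8.30
I C 15N 119.90
I C 13Ca 61.10
I C 1Ha 4.17
I C 1HN 8.00
K H 15N 119.40
K H 13Ca 58.80
K H 1Ha 3.94
K H 1HN 8.09
K E 15N 121.90
K E 13Ca 54.80
K E 1Ha 4.70
K E 1HN 8.59
K C 15N 120.40
K C 13Ca 56.20
K C 1Ha 4.32
K C 1HN 8.29
L H 15N 120.80
L H 13Ca 57.70
L H 1Ha 3.96
L H 1HN 7.96
L E 15N 123.30
L E 13Ca 53.70
L E 1Ha 4.72
L E 1HN 8.46
L C 15N 121.80
L C 13Ca 55.10
L C 1Ha 4.34
L C 1HN 8.16
M H 15N 118.60
M H 13Ca 58.00
M H 1Ha 4.10
M H 1HN 8.08
M E 15N 121.10
M E 13Ca 54.00
M E 1Ha 4.86
M E 1HN 8.58
M C 15N 119.60
M C 13Ca 55.40
M C 1Ha 4.48
M C 1HN 8.28
N H 15N 117.70
N H 13Ca 55.70
N H 1Ha 4.36
N H 1HN 8.20
N E 15N 120.20
N E 13Ca 51.70
N E 1Ha 5.12
N E 1HN 8.70
N C 15N 118.70
N C 13Ca 53.10
N C 1Ha 4.74
N C 1HN 8.40
P H 15N 135.80
P H 13Ca 65.90
P H 1Ha 4.04
P H 1HN 8.10
P E 15N 138.30
P E 13Ca 61.90
P E 1Ha 4.80
P E 1HN 8.60
P C 15N 136.80
P C 13Ca 63.30
P C 1Ha 4.42
P C 1HN 8.30
Q H 15N 118.80
Q H 13Ca 58.30
Q H 1Ha 3.96
Q H 1HN 8.12
Q E 15N 121.30
Q E 13Ca 54.30
Q E 1Ha 4.72
Q E 1HN 8.62
Q C 15N 119.80
Q C 13Ca 55.70
Q C 1Ha 4.34
Q C 1HN 8.32
R H 15N 119.50
R H 13Ca 58.60
R H 1Ha 3.96
R H 1HN 8.03
R E 15N 122.00
R E 13Ca 54.60
R E 1Ha 4.72
R E 1HN 8.53
R C 15N 120.50
R C 13Ca 56.00
R C 1Ha 4.34
R C 1HN 8.23
S H 15N 114.70
S H 13Ca 60.90
S H 1Ha 4.09
S H 1HN 8.11
S E 15N 117.20
S E 13Ca 56.90
S E 1Ha 4.85
S E 1HN 8.61
S C 15N 115.70
S C 13Ca 58.30
S C 1Ha 4.47
S C 1HN 8.31
T H 15N 112.60
T H 13Ca 64.40
T H 1Ha 3.97
T H 1HN 7.95
T E 15N 115.10
T E 13Ca 60.40
T E 1Ha 4.73
T E 1HN 8.45
T C 15N 113.60
T C 13Ca 61.80
T C 1Ha 4.35
T C 1HN 8.15
V H 15N 118.20
V H 13Ca 64.80
V H 1Ha 3.74
V H 1HN 7.83
V E 15N 120.70
V E 13Ca 60.80
V E 1Ha 4.50
V E 1HN 8.33
V C 15N 119.20
V C 13Ca 62.20
V C 1Ha 4.12
V C 1HN 8.03
W H 15N 120.30
W H 13Ca 60.10
W H 1Ha 4.28
W H 1HN 8.05
W E 15N 122.80
W E 13Ca 56.10
W E 1Ha 5.04
W E 1HN 8.55
W C 15N 121.30
W C 13Ca 57.50
W C 1Ha 4.66
W C 1HN 8.25
Y H 15N 119.30
Y H 13Ca 60.50
Y H 1Ha 4.17
Y H 1HN 7.92
Y E 15N 121.80
Y E 13Ca 56.50
Y E 1Ha 4.93
Y E 1HN 8.42
Y C 15N 120.30
Y C 13Ca 57.90
Y C 1Ha 4.55
Y C 1HN 8.12
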
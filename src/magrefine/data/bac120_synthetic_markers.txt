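# Synthetic placeholder identifiers for the default bacterial single-copy
# marker-gene set (120 markers, mirroring the size of the GTDB bac120 set).
# Replace with the real GTDB marker accessions matching your HMM library
# for real analyses; scoring depends only on set membership.
BAC120_001
BAC120_002
BAC120_003
BAC120_004
BAC120_005
BAC120_006
BAC120_007
BAC120_008
BAC120_009
BAC120_010
BAC120_011
BAC120_012
BAC120_013
BAC120_014
BAC120_015
BAC120_016
BAC120_017
BAC120_018
BAC120_019
BAC120_020
BAC120_021
BAC120_022
BAC120_023
BAC120_024
BAC120_025
BAC120_026
BAC120_027
BAC120_028
BAC120_029
BAC120_030
BAC120_031
BAC120_032
BAC120_033
BAC120_034
BAC120_035
BAC120_036
BAC120_037
BAC120_038
BAC120_039
BAC120_040
BAC120_041
BAC120_042
BAC120_043
BAC120_044
BAC120_045
BAC120_046
BAC120_047
BAC120_048
BAC120_049
BAC120_050
BAC120_051
BAC120_052
BAC120_053
BAC120_054
BAC120_055
BAC120_056
BAC120_057
BAC120_058
BAC120_059
BAC120_060
BAC120_061
BAC120_062
BAC120_063
BAC120_064
BAC120_065
BAC120_066
BAC120_067
BAC120_068
BAC120_069
BAC120_070
BAC120_071
BAC120_072
BAC120_073
BAC120_074
BAC120_075
BAC120_076
BAC120_077
BAC120_078
BAC120_079
BAC120_080
BAC120_081
BAC120_082
BAC120_083
BAC120_084
BAC120_085
BAC120_086
BAC120_087
BAC120_088
BAC120_089
BAC120_090
BAC120_091
BAC120_092
BAC120_093
BAC120_094
BAC120_095
BAC120_096
BAC120_097
BAC120_098
BAC120_099
BAC120_100
BAC120_101
BAC120_102
BAC120_103
BAC120_104
BAC120_105
BAC120_106
BAC120_107
BAC120_108
BAC120_109
BAC120_110
BAC120_111
BAC120_112
BAC120_113
BAC120_114
BAC120_115
BAC120_116
BAC120_117
BAC120_118
BAC120_119
BAC120_120
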
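participant,group,orientation,separation,difference
AMD1,MD,collinear,3,-0.122
AMD1,MD,collinear,4,-0.097
AMD1,MD,collinear,6,-0.107
AMD1,MD,collinear,8,-0.148
AMD1,MD,orthogonal,3,-0.115
AMD1,MD,orthogonal,4,-0.155
AMD1,MD,orthogonal,6,-0.101
AMD1,MD,orthogonal,8,-0.179
AMD2,MD,collinear,3,-0.307
AMD2,MD,collinear,4,-0.181
AMD2,MD,collinear,6,-0.102
AMD2,MD,collinear,8,-0.121
AMD2,MD,orthogonal,3,-0.087
AMD2,MD,orthogonal,4,-0.081
AMD2,MD,orthogonal,6,-0.071
AMD2,MD,orthogonal,8,-0.176
AMD3,MD,collinear,3,-0.130
AMD3,MD,collinear,4,-0.048
AMD3,MD,collinear,6,-0.065
AMD3,MD,collinear,8,-0.160
AMD3,MD,orthogonal,3,-0.034
AMD3,MD,orthogonal,4,-0.084
AMD3,MD,orthogonal,6,-0.057
AMD3,MD,orthogonal,8,-0.158
AMD4,MD,collinear,3,-0.083
AMD4,MD,collinear,4,-0.108
AMD4,MD,collinear,6,-0.114
AMD4,MD,collinear,8,-0.064
AMD4,MD,orthogonal,3,-0.017
AMD4,MD,orthogonal,4,-0.068
AMD4,MD,orthogonal,6,-0.045
AMD4,MD,orthogonal,8,-0.078
C1,control,collinear,3,-0.092
C1,control,collinear,4,0.017
C1,control,collinear,6,-0.002
C1,control,collinear,8,-0.014
C1,control,orthogonal,3,-0.006
C1,control,orthogonal,4,-0.006
C1,control,orthogonal,6,-0.116
C1,control,orthogonal,8,-0.007
C2,control,collinear,3,-0.070
C2,control,collinear,4,-0.033
C2,control,collinear,6,0.003
C2,control,collinear,8,-0.022
C2,control,orthogonal,3,-0.022
C2,control,orthogonal,4,-0.009
C2,control,orthogonal,6,-0.019
C2,control,orthogonal,8,-0.054
C4,control,collinear,3,0.044
C4,control,collinear,4,-0.040
C4,control,collinear,6,0.011
C4,control,collinear,8,-0.013
C4,control,orthogonal,3,-0.012
C4,control,orthogonal,4,-0.001
C4,control,orthogonal,6,-0.001
C4,control,orthogonal,8,-0.012
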
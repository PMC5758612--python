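participant,group,phase,orientation,separation,threshold
AMD1,MD,pre,collinear,3,0.217
AMD1,MD,pre,collinear,4,0.170
AMD1,MD,pre,collinear,6,0.210
AMD1,MD,pre,collinear,8,0.238
AMD1,MD,pre,orthogonal,3,0.229
AMD1,MD,pre,orthogonal,4,0.270
AMD1,MD,pre,orthogonal,6,0.215
AMD1,MD,pre,orthogonal,8,0.280
AMD2,MD,pre,collinear,3,0.486
AMD2,MD,pre,collinear,4,0.316
AMD2,MD,pre,collinear,6,0.193
AMD2,MD,pre,collinear,8,0.230
AMD2,MD,pre,orthogonal,3,0.242
AMD2,MD,pre,orthogonal,4,0.257
AMD2,MD,pre,orthogonal,6,0.211
AMD2,MD,pre,orthogonal,8,0.282
AMD3,MD,pre,collinear,3,0.355
AMD3,MD,pre,collinear,4,0.204
AMD3,MD,pre,collinear,6,0.171
AMD3,MD,pre,collinear,8,0.274
AMD3,MD,pre,orthogonal,3,0.246
AMD3,MD,pre,orthogonal,4,0.216
AMD3,MD,pre,orthogonal,6,0.215
AMD3,MD,pre,orthogonal,8,0.289
AMD4,MD,pre,collinear,3,0.122
AMD4,MD,pre,collinear,4,0.177
AMD4,MD,pre,collinear,6,0.164
AMD4,MD,pre,collinear,8,0.110
AMD4,MD,pre,orthogonal,3,0.071
AMD4,MD,pre,orthogonal,4,0.121
AMD4,MD,pre,orthogonal,6,0.221
AMD4,MD,pre,orthogonal,8,0.143
AMD5,MD,pre,collinear,3,0.492
AMD5,MD,pre,collinear,4,0.229
AMD5,MD,pre,collinear,6,0.094
AMD5,MD,pre,collinear,8,0.090
AMD5,MD,pre,orthogonal,3,0.201
AMD5,MD,pre,orthogonal,4,0.241
AMD5,MD,pre,orthogonal,6,0.105
AMD5,MD,pre,orthogonal,8,0.120
C1,control,pre,collinear,3,0.201
C1,control,pre,collinear,4,0.078
C1,control,pre,collinear,6,0.048
C1,control,pre,collinear,8,0.056
C1,control,pre,orthogonal,3,0.065
C1,control,pre,orthogonal,4,0.056
C1,control,pre,orthogonal,6,0.071
C1,control,pre,orthogonal,8,0.101
C2,control,pre,collinear,3,0.140
C2,control,pre,collinear,4,0.028
C2,control,pre,collinear,6,0.026
C2,control,pre,collinear,8,0.029
C2,control,pre,orthogonal,3,0.026
C2,control,pre,orthogonal,4,0.037
C2,control,pre,orthogonal,6,0.035
C2,control,pre,orthogonal,8,0.033
C3,control,pre,collinear,3,0.371
C3,control,pre,collinear,4,0.413
C3,control,pre,collinear,6,0.141
C3,control,pre,collinear,8,0.104
C3,control,pre,orthogonal,3,0.208
C3,control,pre,orthogonal,4,0.171
C3,control,pre,orthogonal,6,0.209
C3,control,pre,orthogonal,8,0.129
C4,control,pre,collinear,3,0.112
C4,control,pre,collinear,4,0.070
C4,control,pre,collinear,6,0.018
C4,control,pre,collinear,8,0.028
C4,control,pre,orthogonal,3,0.041
C4,control,pre,orthogonal,4,0.029
C4,control,pre,orthogonal,6,0.026
C4,control,pre,orthogonal,8,0.037
C5,control,pre,collinear,3,0.180
C5,control,pre,collinear,4,0.093
C5,control,pre,collinear,6,0.056
C5,control,pre,collinear,8,0.060
C5,control,pre,orthogonal,3,0.067
C5,control,pre,orthogonal,4,0.095
C5,control,pre,orthogonal,6,0.134
C5,control,pre,orthogonal,8,0.124
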
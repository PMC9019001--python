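bout_id,pollinator_id,visit_index,plant_id
butterfly-b1,butterfly,1,focal
butterfly-b1,butterfly,2,other
butterfly-b1,butterfly,3,other
butterfly-b1,butterfly,4,other
butterfly-b1,butterfly,5,other
butterfly-b1,butterfly,6,other
butterfly-b1,butterfly,7,other
butterfly-b1,butterfly,8,focal
butterfly-b10,butterfly,1,focal
butterfly-b10,butterfly,2,focal
butterfly-b10,butterfly,3,focal
butterfly-b10,butterfly,4,focal
butterfly-b10,butterfly,5,focal
butterfly-b10,butterfly,6,focal
butterfly-b10,butterfly,7,other
butterfly-b10,butterfly,8,focal
butterfly-b11,butterfly,1,focal
butterfly-b11,butterfly,2,other
butterfly-b11,butterfly,3,other
butterfly-b11,butterfly,4,other
butterfly-b11,butterfly,5,focal
butterfly-b11,butterfly,6,focal
butterfly-b11,butterfly,7,other
butterfly-b11,butterfly,8,focal
butterfly-b12,butterfly,1,focal
butterfly-b12,butterfly,2,other
butterfly-b12,butterfly,3,other
butterfly-b12,butterfly,4,focal
butterfly-b12,butterfly,5,focal
butterfly-b12,butterfly,6,focal
butterfly-b12,butterfly,7,focal
butterfly-b12,butterfly,8,focal
butterfly-b2,butterfly,1,focal
butterfly-b2,butterfly,2,focal
butterfly-b2,butterfly,3,focal
butterfly-b2,butterfly,4,focal
butterfly-b2,butterfly,5,other
butterfly-b2,butterfly,6,other
butterfly-b2,butterfly,7,other
butterfly-b2,butterfly,8,other
butterfly-b3,butterfly,1,focal
butterfly-b3,butterfly,2,focal
butterfly-b3,butterfly,3,other
butterfly-b3,butterfly,4,focal
butterfly-b3,butterfly,5,other
butterfly-b3,butterfly,6,other
butterfly-b3,butterfly,7,focal
butterfly-b3,butterfly,8,focal
butterfly-b4,butterfly,1,other
butterfly-b4,butterfly,2,focal
butterfly-b4,butterfly,3,focal
butterfly-b4,butterfly,4,focal
butterfly-b4,butterfly,5,focal
butterfly-b4,butterfly,6,other
butterfly-b4,butterfly,7,other
butterfly-b4,butterfly,8,other
butterfly-b5,butterfly,1,other
butterfly-b5,butterfly,2,other
butterfly-b5,butterfly,3,other
butterfly-b5,butterfly,4,other
butterfly-b5,butterfly,5,other
butterfly-b5,butterfly,6,focal
butterfly-b5,butterfly,7,other
butterfly-b5,butterfly,8,other
butterfly-b6,butterfly,1,other
butterfly-b6,butterfly,2,focal
butterfly-b6,butterfly,3,focal
butterfly-b6,butterfly,4,focal
butterfly-b6,butterfly,5,focal
butterfly-b6,butterfly,6,focal
butterfly-b6,butterfly,7,focal
butterfly-b6,butterfly,8,focal
butterfly-b7,butterfly,1,focal
butterfly-b7,butterfly,2,focal
butterfly-b7,butterfly,3,focal
butterfly-b7,butterfly,4,focal
butterfly-b7,butterfly,5,focal
butterfly-b7,butterfly,6,focal
butterfly-b7,butterfly,7,focal
butterfly-b7,butterfly,8,other
butterfly-b8,butterfly,1,focal
butterfly-b8,butterfly,2,focal
butterfly-b8,butterfly,3,focal
butterfly-b8,butterfly,4,focal
butterfly-b8,butterfly,5,focal
butterfly-b8,butterfly,6,other
butterfly-b8,butterfly,7,other
butterfly-b8,butterfly,8,other
butterfly-b9,butterfly,1,other
butterfly-b9,butterfly,2,other
butterfly-b9,butterfly,3,other
butterfly-b9,butterfly,4,other
butterfly-b9,butterfly,5,focal
butterfly-b9,butterfly,6,focal
butterfly-b9,butterfly,7,focal
butterfly-b9,butterfly,8,focal
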
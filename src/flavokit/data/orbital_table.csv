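compound,e_homo,e_lumo,i,a,source
blumeatin,-6.56,-1.73,6.32,1.48,this work
quercetin,-5.03,-2.49,5.03,2.49,ref77
quercetin,-5.88,-2.10,5.88,2.10,ref78
taxifolin,-5.44,-2.46,5.44,2.46,ref78
luteolin,-5.93,-1.67,5.93,1.67,ref79
gallic acid,-1.23,0.24,1.23,-0.24,ref80
betulinic acid,-6.47,0.17,6.47,-0.17,ref80
lupeol,-6.31,0.76,6.31,-0.76,ref80
procyanidin,-0.04,0.02,0.04,-0.02,ref80
foeniculin,-0.34,-0.16,0.34,0.16,ref80
morin,-7.17,-0.68,7.17,6.68,ref81
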
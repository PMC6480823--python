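variable,NS1,NS2,AN1,AN2,UN1,UN2,Math,Eng
NS1,4.456,,,,,,,
NS2,0.787,4.487,,,,,,
AN1,0.348,0.297,4.496,,,,,
AN2,0.376,0.347,0.687,4.045,,,,
UN1,0.383,0.378,0.295,0.366,5.168,,,
UN2,0.282,0.319,0.224,0.239,0.688,5.539,,
Math,0.349,0.350,0.289,0.378,0.302,0.275,1.0,
Eng,0.225,0.205,0.263,0.241,0.135,0.097,0.469,1.0
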
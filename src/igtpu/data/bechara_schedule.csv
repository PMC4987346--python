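deck,position,gain,loss
A,1,100,0
A,2,100,0
A,3,100,-150
A,4,100,0
A,5,100,-300
A,6,100,0
A,7,100,-200
A,8,100,0
A,9,100,-250
A,10,100,-350
A,11,100,0
A,12,100,0
A,13,100,-150
A,14,100,0
A,15,100,-300
A,16,100,0
A,17,100,-200
A,18,100,0
A,19,100,-250
A,20,100,-350
A,21,100,0
A,22,100,0
A,23,100,-150
A,24,100,0
A,25,100,-300
A,26,100,0
A,27,100,-200
A,28,100,0
A,29,100,-250
A,30,100,-350
A,31,100,0
A,32,100,0
A,33,100,-150
A,34,100,0
A,35,100,-300
A,36,100,0
A,37,100,-200
A,38,100,0
A,39,100,-250
A,40,100,-350
B,1,100,0
B,2,100,0
B,3,100,0
B,4,100,0
B,5,100,0
B,6,100,0
B,7,100,0
B,8,100,0
B,9,100,-1250
B,10,100,0
B,11,100,0
B,12,100,0
B,13,100,0
B,14,100,0
B,15,100,0
B,16,100,0
B,17,100,0
B,18,100,0
B,19,100,-1250
B,20,100,0
B,21,100,0
B,22,100,0
B,23,100,0
B,24,100,0
B,25,100,0
B,26,100,0
B,27,100,0
B,28,100,0
B,29,100,-1250
B,30,100,0
B,31,100,0
B,32,100,0
B,33,100,0
B,34,100,0
B,35,100,0
B,36,100,0
B,37,100,0
B,38,100,0
B,39,100,-1250
B,40,100,0
C,1,50,0
C,2,50,0
C,3,50,-50
C,4,50,0
C,5,50,-50
C,6,50,0
C,7,50,-50
C,8,50,0
C,9,50,-50
C,10,50,-50
C,11,50,0
C,12,50,0
C,13,50,-50
C,14,50,0
C,15,50,-50
C,16,50,0
C,17,50,-50
C,18,50,0
C,19,50,-50
C,20,50,-50
C,21,50,0
C,22,50,0
C,23,50,-50
C,24,50,0
C,25,50,-50
C,26,50,0
C,27,50,-50
C,28,50,0
C,29,50,-50
C,30,50,-50
C,31,50,0
C,32,50,0
C,33,50,-50
C,34,50,0
C,35,50,-50
C,36,50,0
C,37,50,-50
C,38,50,0
C,39,50,-50
C,40,50,-50
D,1,50,0
D,2,50,0
D,3,50,0
D,4,50,0
D,5,50,0
D,6,50,0
D,7,50,0
D,8,50,0
D,9,50,0
D,10,50,-250
D,11,50,0
D,12,50,0
D,13,50,0
D,14,50,0
D,15,50,0
D,16,50,0
D,17,50,0
D,18,50,0
D,19,50,0
D,20,50,-250
D,21,50,0
D,22,50,0
D,23,50,0
D,24,50,0
D,25,50,0
D,26,50,0
D,27,50,0
D,28,50,0
D,29,50,0
D,30,50,-250
D,31,50,0
D,32,50,0
D,33,50,0
D,34,50,0
D,35,50,0
D,36,50,0
D,37,50,0
D,38,50,0
D,39,50,0
D,40,50,-250
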
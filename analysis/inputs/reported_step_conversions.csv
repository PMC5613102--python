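substrate,product,elongation,elovl4a,elovl4b
18:4n-3,20:4n-3,C18 -> 20,3.7,2.0
18:4n-3,22:4n-3,C20 -> 22,26.8,6.4
18:4n-3,24:4n-3,C22 -> 24,53.1,7.9
18:4n-3,26:4n-3,C24 -> 26,62.9,6.8
18:4n-3,28:4n-3,C26 -> 28,100,3.7
18:4n-3,30:4n-3,C28 -> 30,100,48.9
18:4n-3,32:4n-3,C30 -> 32,91.2,48.4
18:4n-3,34:4n-3,C32 -> 34,83.6,1.4
18:4n-3,36:4n-3,C34 -> 36,7.7,ND
18:3n-6,20:3n-6,C18 -> 20,6.0,3.0
18:3n-6,22:3n-6,C20 -> 22,49.5,9.9
18:3n-6,24:3n-6,C22 -> 24,73.2,12.2
18:3n-6,26:3n-6,C24 -> 26,80.2,29.4
18:3n-6,28:3n-6,C26 -> 28,100,100
18:3n-6,30:3n-6,C28 -> 30,100,100
18:3n-6,32:3n-6,C30 -> 32,100,51.7
18:3n-6,34:3n-6,C32 -> 34,69.5,ND
18:3n-6,36:3n-6,C34 -> 36,8.1,ND
20:5n-3,22:5n-3,C20 -> 22,20.4,6.3
20:5n-3,24:5n-3,C22 -> 24,41.4,13.2
20:5n-3,26:5n-3,C24 -> 26,55.8,4.7
20:5n-3,28:5n-3,C26 -> 28,100,100
20:5n-3,30:5n-3,C28 -> 30,100,19.3
20:5n-3,32:5n-3,C30 -> 32,83.3,69.9
20:5n-3,34:5n-3,C32 -> 34,93.4,12.0
20:5n-3,36:5n-3,C34 -> 36,48.1,ND
20:4n-6,22:4n-6,C20 -> 22,26.0,7.5
20:4n-6,24:4n-6,C22 -> 24,54.6,15.9
20:4n-6,26:4n-6,C24 -> 26,70.4,10.9
20:4n-6,28:4n-6,C26 -> 28,85.4,9.9
20:4n-6,30:4n-6,C28 -> 30,99.2,63.1
20:4n-6,32:4n-6,C30 -> 32,96.5,28.4
20:4n-6,34:4n-6,C32 -> 34,87.1,ND
20:4n-6,36:4n-6,C34 -> 36,27.4,ND
22:5n-3,24:5n-3,C22 -> 24,14.2,5.2
22:5n-3,26:5n-3,C24 -> 26,51.1,3.9
22:5n-3,28:5n-3,C26 -> 28,83.4,2.4
22:5n-3,30:5n-3,C28 -> 30,98.3,31.0
22:5n-3,32:5n-3,C30 -> 32,96.5,64.4
22:5n-3,34:5n-3,C32 -> 34,89.8,5.6
22:5n-3,36:5n-3,C34 -> 36,34.3,ND
22:4n-6,24:4n-6,C22 -> 24,19.1,7.6
22:4n-6,26:4n-6,C24 -> 26,69.9,9.9
22:4n-6,28:4n-6,C26 -> 28,87.0,9.3
22:4n-6,30:4n-6,C28 -> 30,99.2,67.7
22:4n-6,32:4n-6,C30 -> 32,96.1,24.0
22:4n-6,34:4n-6,C32 -> 34,83.8,ND
22:4n-6,36:4n-6,C34 -> 36,24.3,ND
22:6n-3,24:6n-3,C22 -> 24,0.8,0.9
22:6n-3,26:6n-3,C24 -> 26,ND,100
22:6n-3,28:6n-3,C26 -> 28,ND,100
22:6n-3,30:6n-3,C28 -> 30,ND,100
22:6n-3,32:6n-3,C30 -> 32,ND,43.7
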
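model_id,full_name,input_size_px,top1_imagenet,top5_imagenet,origin_library,n_params,flop_millions
AlxNet,AlexNet,227,57.2,80.3,Caffe,60965224,1450.58
DnsNet_121,DenseNet 121,224,74.9,92.2,Keras,8062505,5439.98
DnsNet_161,DenseNet 161,224,77.6,93.8,Keras,28900937,15113.90
DnsNet_169,DenseNet 169,224,76.1,93.1,Keras,14307881,6491.70
Inc_Res_v2,Inception-Resnet version 2,224,80.4,95.3,Tensorflow,59244595,2776.56
Inc_v1,Inception version 1,224,69.8,89.6,Tensorflow,6633210,3856.10
Inc_v2,Inception version 2,224,73.9,91.8,Tensorflow,11199138,11421.58
Inc_v3,Inception version 3,299,78.0,93.9,Tensorflow,27182195,24529.78
Inc_v4,Inception version 4,299,80.2,95.2,Tensorflow,46074067,26330.24
Mob_v1_0.25,MobileNet version 1 0.25,224,49.8,74.2,Tensorflow,1892263,77.44
Mob_v1_0.50,MobileNet version 1 0.50,224,63.3,84.9,Tensorflow,5350311,289.74
Mob_v1_0.75,MobileNet version 1 0.75,224,68.4,88.2,Tensorflow,10378151,636.92
Mob_v1_1.0,MobileNet version 1 1.0,224,70.9,89.9,Tensorflow,16975783,1118.98
Mob_v2_0.35,MobileNet version 2 0.35,224,60.3,82.9,Tensorflow,6727717,109.80
Mob_v2_0.50,MobileNet version 2 0.50,224,65.4,86.4,Tensorflow,7898389,186.02
Mob_v2_0.75,MobileNet version 2 0.75,224,69.8,89.6,Tensorflow,10577461,406.04
Mob_v2_1.0,MobileNet version 2 1.0,224,71.8,91.0,Tensorflow,14058725,584.54
Mob_v2_1.3,MobileNet version 2 1.3,224,74.4,92.1,Tensorflow,21598085,997.98
Mob_v2_1.4,MobileNet version 2 1.4,224,75.0,92.5,Tensorflow,24490213,1138.56
Mob_v3_lrg,MobileNet version 3 1.0 large,224,75.2,,Tensorflow,16501740,431.58
Mob_v3_lrgm,MobileNet version 3 1.0 large minimalistic,224,72.3,,Tensorflow,15751077,410.94
Mob_v3_sml,MobileNet version 3 1.0 small,224,67.5,,Tensorflow,10199749,106.24
Mob_v3_smlm,MobileNet version 3 1.0 small minimalistic,224,61.9,,Tensorflow,8207269,94.82
Ns_lrg,NasNet large,331,82.7,96.2,Tensorflow,187048393,47607.92
Ns_mob,NasNet mobile,224,74.0,91.6,Tensorflow,15483149,1121.80
Pns_lrg,PnasNet-5 large,331,82.9,96.2,Tensorflow,181655509,49896.78
Pns_mob,PnasNet-5 mobile,224,74.2,91.9,Tensorflow,15029139,1168.20
Rs_v1_50,ResNet 50 version 1,224,75.2,92.2,Caffe,25610156,6744.48
Rs_v1_101,ResNet 101 version 1,224,76.4,92.9,Caffe,44654508,14177.45
Rs_v1_152,ResNet 152 version 1,224,76.8,93.2,Caffe,60344236,21612.43
Rs_v2_50,ResNet 50 version 2,299,75.6,92.8,Tensorflow,76802109,6744.49
Rs_v2_101,ResNet 101 version 2,299,77.0,93.7,Tensorflow,133935165,14177.46
Rs_v2_152,ResNet 152 version 2,299,77.8,94.1,Tensorflow,181004349,21612.44
Vgg_16,VGG 16,224,71.5,89.8,Caffe,138357548,30786.80
Vgg_19,VGG 19,224,71.1,89.8,Caffe,143667244,39111.70
Xcp_v1,Xception version 1,299,79.0,94.5,Keras,22910480,16731.28
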